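"""k-means clustering under squared-Euclidean, cosine, or correlation
distance, with model-seeded or repeated random initialization.

For cosine and correlation distances, members are normalized (unit norm
after, for correlation, centering across the 30 coordinates) and the
centroid of a cluster is the mean of its normalized members; assignment
uses the chosen distance between normalized members and normalized
centroids.  Correlation-distance clustering is therefore invariant to
per-vector affine rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stndecide.cluster.seeds import SeedSet

__all__ = ["ClusterModel", "kmeans_fit", "assign_by_correlation"]

DISTANCES = ("sq-euclidean", "cosine", "correlation")


def _normalize(X: np.ndarray, distance: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if distance == "sq-euclidean":
        return X
    if distance == "cosine":
        n = np.linalg.norm(X, axis=-1, keepdims=True)
    elif distance == "correlation":
        X = X - X.mean(axis=-1, keepdims=True)
        n = np.linalg.norm(X, axis=-1, keepdims=True)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return X / np.where(n > 0, n, 1.0)


def _dist_matrix(Xn: np.ndarray, Cn: np.ndarray, distance: str) -> np.ndarray:
    if distance == "sq-euclidean":
        return (
            np.sum(Xn**2, axis=1)[:, None]
            - 2.0 * Xn @ Cn.T
            + np.sum(Cn**2, axis=1)[None, :]
        )
    # cosine / correlation on pre-normalized rows
    return 1.0 - Xn @ _normalize(Cn, "cosine").T


@dataclass
class ClusterModel:
    """Result of one k-means fit."""

    k: int
    distance: str
    assignments: np.ndarray  # labels in 1..k
    centroids: np.ndarray  # (k, d); normalized space for cosine/correlation
    inertia: float
    n_reps: int
    init: str

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "distance": self.distance,
            "assignments": self.assignments.tolist(),
            "centroids": self.centroids.tolist(),
            "inertia": self.inertia,
            "n_reps": self.n_reps,
            "init": self.init,
        }


def _plusplus_init(Xn, k, distance, rng):
    n = len(Xn)
    idx = [int(rng.integers(n))]
    d = _dist_matrix(Xn, Xn[idx[-1]][None, :], distance)[:, 0]
    for _ in range(k - 1):
        d = np.maximum(d, 0.0)
        tot = d.sum()
        if tot <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d / tot)))
        d = np.minimum(d, _dist_matrix(Xn, Xn[idx[-1]][None, :], distance)[:, 0])
    return Xn[idx].copy()


def _lloyd(Xn, C, distance, max_iter, rng):
    n, k = len(Xn), len(C)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        D = _dist_matrix(Xn, C, distance)
        new_labels = D.argmin(axis=1)
        # empty-cluster policy: re-seed the centroid at the worst-fit point
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(D[np.arange(n), new_labels].argmax())
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            C[j] = Xn[labels == j].mean(axis=0)
    D = _dist_matrix(Xn, C, distance)
    inertia = float(D[np.arange(n), labels].sum())
    return labels, C, inertia


def kmeans_fit(
    vectors: np.ndarray,
    k: int,
    distance: str = "correlation",
    init: SeedSet | np.ndarray | str = "random",
    n_reps: int = 100,
    seed: int = 0,
    max_iter: int = 100,
) -> ClusterModel:
    """k-means clustering, best of ``n_reps`` repetitions.

    ``init`` may be ``"random"`` (k-means++ seeding per repetition), a
    :class:`SeedSet`, or an array of initial centroids; with explicit
    seeds the solution is deterministic and a single repetition is run.
    Assignments are labeled 1..k.  Deterministic given ``seed``.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or len(X) < k:
        raise ValueError("need at least k vectors")
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    Xn = _normalize(X, distance)
    rng = np.random.default_rng(seed)

    if isinstance(init, SeedSet):
        C0, init_name, reps = _normalize(init.vectors, distance), "model-seeds", 1
        if len(C0) != k:
            raise ValueError(f"SeedSet provides {len(C0)} seeds but k={k}")
    elif isinstance(init, np.ndarray):
        C0, init_name, reps = _normalize(init, distance), "explicit", 1
        if len(C0) != k:
            raise ValueError("init centroids must have k rows")
    elif init == "random":
        C0, init_name, reps = None, "random", n_reps
    else:
        raise ValueError(f"unknown init {init!r}")

    best = None
    for _ in range(reps):
        C = _plusplus_init(Xn, k, distance, rng) if C0 is None else C0.copy()
        labels, C, inertia = _lloyd(Xn, C, distance, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, C, inertia)
    labels, C, inertia = best
    return ClusterModel(
        k=k,
        distance=distance,
        assignments=labels + 1,
        centroids=C,
        inertia=inertia,
        n_reps=reps,
        init=init_name,
    )


def assign_by_correlation(vector: np.ndarray, centroids: np.ndarray) -> int:
    """Cluster label (1-based) of the centroid with the highest Pearson
    correlation to ``vector``; ties break toward the lowest label."""
    v = np.asarray(vector, dtype=float)
    vc = v - v.mean()
    nv = np.linalg.norm(vc)
    if nv == 0:
        raise ValueError("correlation undefined for a constant vector")
    C = np.asarray(centroids, dtype=float)
    Cc = C - C.mean(axis=1, keepdims=True)
    nc = np.linalg.norm(Cc, axis=1)
    if np.any(nc == 0):
        raise ValueError("correlation undefined for a constant centroid")
    r = (Cc @ vc) / (nc * nv)
    return int(np.argmax(r)) + 1
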