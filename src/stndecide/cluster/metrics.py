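"""Cluster quality and stability metrics: silhouette and Rand index.

The silhouette score of a member is

    (D_inter - D_intra) / max(D_inter, D_intra)

where D_intra is its average distance to other members of its own
cluster and D_inter its average distance to the members of its nearest
neighboring cluster.  Degenerate conventions: singleton clusters and
all-zero distances score 0.

The Rand index of two partitions is the fraction of item pairs on which
they agree (co-clustered in both, or separated in both); it is invariant
to label permutations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["silhouette", "rand_index", "spatial_silhouette"]

_METRIC = {"sq-euclidean": "sqeuclidean", "euclidean": "euclidean",
           "cosine": "cosine", "correlation": "correlation"}


def silhouette(vectors: np.ndarray, assignments, distance: str = "correlation"):
    """Per-member silhouette scores under the chosen distance."""
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if distance not in _METRIC:
        raise ValueError(f"unknown distance {distance!r}")
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(X, metric=_METRIC[distance]))
    D = np.nan_to_num(D, nan=0.0)  # constant rows under correlation
    n = len(X)
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum() - 1
        if n_own == 0:
            scores[i] = 0.0  # singleton convention
            continue
        d_intra = D[i, own].sum() / n_own
        d_inter = min(
            D[i, labels == u].mean() for u in uniq if u != labels[i]
        )
        denom = max(d_inter, d_intra)
        scores[i] = 0.0 if denom == 0 else (d_inter - d_intra) / denom
    return scores


def rand_index(assign_a, assign_b) -> float:
    """Pair-counting agreement between two partitions, in [0, 1]."""
    a = np.asarray(assign_a)
    b = np.asarray(assign_b)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    # contingency-based pair counting
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nij = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(nij, (ai, bi), 1)

    def c2(x):
        return (x * (x - 1.0) / 2.0).sum()

    total = n * (n - 1.0) / 2.0
    same_same = c2(nij)
    same_a = c2(nij.sum(axis=1))
    same_b = c2(nij.sum(axis=0))
    return float((total + 2.0 * same_same - same_a - same_b) / total)


def spatial_silhouette(locations: np.ndarray, labels) -> float:
    """Mean Euclidean silhouette of anatomical positions grouped by
    activity-cluster labels.

    Positive values mean the activity clusters also segregate in physical
    (AP, ML, depth) space; values near zero or negative mean they are
    spatially intermingled.
    """
    loc = np.asarray(locations, dtype=float)
    if loc.ndim != 2:
        raise ValueError("locations must be (n, 3)")
    return float(np.mean(silhouette(loc, labels, distance="euclidean")))
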