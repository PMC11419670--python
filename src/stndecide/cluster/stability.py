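"""Cluster-stability grid: repeated k-means over settings, scored by the
mean pairwise Rand index across runs and by silhouette summaries.

For each setting (representation x distance x k), the k-means algorithm
is run ``n_runs`` times with distinct sub-seeds, each run keeping the
best of ``n_reps`` random-init repetitions; stability is the mean Rand
index over all run pairs.  The chosen setting maximizes mean Rand, with
ties broken by higher mean silhouette and then fewer negative scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from stndecide.cluster.kmeans import DISTANCES, kmeans_fit
from stndecide.cluster.metrics import rand_index, silhouette

__all__ = ["StabilityReport", "stability_grid", "pc_projection"]


def pc_projection(X: np.ndarray, min_variance: float = 0.95):
    """Project onto the smallest number of principal components whose
    cumulative explained variance reaches ``min_variance``."""
    pca = PCA()
    Z = pca.fit_transform(np.asarray(X, dtype=float))
    n_comp = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), min_variance) + 1)
    return Z[:, :n_comp], n_comp


@dataclass
class StabilityReport:
    """Per-setting stability and quality summary."""

    table: pd.DataFrame  # representation, distance, k, mean_rand, ...
    chosen: dict
    n_runs: int
    n_reps: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "chosen": dict(self.chosen),
            "n_runs": self.n_runs,
            "n_reps": self.n_reps,
            "flags": list(self.flags),
        }


def stability_grid(
    vectors: np.ndarray,
    representations=("raw30", "pcs"),
    distances=DISTANCES,
    ks=tuple(range(3, 10)),
    n_runs: int = 50,
    n_reps: int = 100,
    seed: int = 0,
) -> StabilityReport:
    """Evaluate clustering stability over the settings grid.

    Returns a report whose table has one row per setting with the mean
    pairwise Rand index, mean silhouette of the best run (by inertia),
    and the count of negative silhouette scores.
    """
    X = np.asarray(vectors, dtype=float)
    if len(X) < max(ks):
        raise ValueError("not enough vectors for the largest k")
    rng = np.random.default_rng(seed)
    flags = []
    if n_runs < 2:
        flags.append("n_runs < 2: pairwise Rand undefined")

    reps_data = {"raw30": X}
    if "pcs" in representations:
        Z, n_comp = pc_projection(X)
        reps_data["pcs"] = Z
        flags.append(f"pcs: {n_comp} components for >=95% variance")

    rows = []
    for rep in representations:
        Xr = reps_data[rep]
        for dist in distances:
            for k in ks:
                runs = []
                for _ in range(n_runs):
                    m = kmeans_fit(
                        Xr, k, distance=dist, init="random",
                        n_reps=n_reps, seed=int(rng.integers(2**31 - 1)),
                    )
                    runs.append(m)
                if n_runs >= 2:
                    mean_rand = float(
                        np.mean(
                            [
                                rand_index(a.assignments, b.assignments)
                                for a, b in combinations(runs, 2)
                            ]
                        )
                    )
                else:
                    mean_rand = np.nan
                best = min(runs, key=lambda m: m.inertia)
                sil = silhouette(Xr, best.assignments, distance=dist)
                rows.append(
                    {
                        "representation": rep,
                        "distance": dist,
                        "k": k,
                        "mean_rand": mean_rand,
                        "mean_silhouette": float(np.mean(sil)),
                        "n_negative_silhouette": int(np.sum(sil < 0)),
                    }
                )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_rand", "mean_silhouette", "n_negative_silhouette"],
        ascending=[False, False, True],
        na_position="last",
    )
    chosen = ranked.iloc[0].to_dict()
    return StabilityReport(
        table=table, chosen=chosen, n_runs=n_runs, n_reps=n_reps, flags=flags
    )
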