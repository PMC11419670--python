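"""30-D condition-averaged activity vectors.

Each neuron's task-related activity is summarized by the average firing
rate in three 200 ms epochs — early motion viewing (100-300 ms after
motion onset), late motion viewing (300-500 ms), and peri-saccade
(100 ms before to 100 ms after saccade onset) — for each of 2 choices x
5 coherence levels, z-scored against the 300 ms pre-motion baseline.

The two choices are relabeled 'preferred'/'other' by the relative
average activity in the peri-saccade window, so neurons with the same
modulation pattern but opposite choice polarity group together.  The
vector ordering is epoch-major:

    index = epoch * 10 + choice * 5 + coherence_rank

with epoch in (early, late, peri-saccade), choice in (preferred, other),
and coherences ascending.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["VECTOR_ORDER", "build_activity_vectors"]

logger = logging.getLogger(__name__)

#: Human-readable labels of the 30 vector entries, in storage order.
VECTOR_ORDER = [
    f"{epoch}_{choice}_c{j + 1}"
    for epoch in ("early", "late", "peri")
    for choice in ("pref", "other")
    for j in range(5)
]

_EPOCHS = {
    "early": ("motion", 100, 200),
    "late": ("motion", 300, 200),
    "peri": ("saccade", -100, 200),
}
_BASELINE = ("motion", -300, 300)


def build_activity_vectors(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    correct_only: bool = True,
) -> pd.DataFrame:
    """Build the 30-D vector for every neuron in a spike-count table.

    ``spikes`` must contain the three epoch windows and the pre-motion
    baseline window (see :data:`stndecide.synth.CANONICAL_WINDOWS`).
    Returns a DataFrame indexed by ``neuron_id`` with columns ``v01`` ..
    ``v30`` and ``preferred_label`` (``contra``/``ipsi``).  Neurons whose
    baseline rate has zero variance are excluded (logged).  Raises
    ``ValueError`` naming the first missing (choice, coherence, epoch)
    condition.
    """
    t = trials[trials["correct"]] if correct_only else trials
    sp = spikes.merge(t[["trial_id", "signed_coh", "choice"]], on="trial_id")
    if len(sp) == 0:
        raise ValueError("no spike rows match the selected trials")
    sp = sp.assign(
        rate=sp["count"] / (sp["window_ms"] / 1000.0),
        coh_mag=np.abs(sp["signed_coh"]),
    )
    mags = np.sort(sp["coh_mag"].unique())
    if len(mags) != 5:
        raise ValueError(f"expected 5 coherence magnitudes, found {len(mags)}")

    def _window_rows(df, win):
        al, start, width = win
        return df[
            (df["alignment"] == al)
            & (df["window_start_ms"] == start)
            & (df["window_ms"] == width)
        ]

    base = _window_rows(sp, _BASELINE)
    bstats = base.groupby("neuron_id")["rate"].agg(["mean", "std"])

    epoch_means = {}
    for name, win in _EPOCHS.items():
        rows = _window_rows(sp, win)
        epoch_means[name] = rows.groupby(["neuron_id", "choice", "coh_mag"])[
            "rate"
        ].mean()

    records = []
    for nid in sorted(sp["neuron_id"].unique()):
        if nid not in bstats.index or not np.isfinite(bstats.loc[nid, "std"]):
            raise ValueError(f"neuron {nid}: baseline window missing")
        mu, sd = bstats.loc[nid, "mean"], bstats.loc[nid, "std"]
        if sd <= 0:
            logger.warning("neuron %s excluded: zero baseline variance", nid)
            continue
        z = np.empty((3, 2, 5))  # epoch x (contra, ipsi) x coherence
        for e, name in enumerate(("early", "late", "peri")):
            em = epoch_means[name]
            for c, choice in enumerate(("contra", "ipsi")):
                for j, mag in enumerate(mags):
                    key = (nid, choice, mag)
                    if key not in em.index:
                        raise ValueError(
                            f"neuron {nid}: no trials for condition "
                            f"(choice={choice}, coherence={mag:g}, epoch={name})"
                        )
                    z[e, c, j] = (em.loc[key] - mu) / sd
        pref_is_contra = z[2, 0, :].mean() >= z[2, 1, :].mean()
        order = (0, 1) if pref_is_contra else (1, 0)
        vec = np.concatenate([z[e, c, :] for e in range(3) for c in order])
        rec = {"neuron_id": nid, "preferred_label": "contra" if pref_is_contra else "ipsi"}
        rec.update({f"v{i + 1:02d}": vec[i] for i in range(30)})
        records.append(rec)
    if not records:
        raise ValueError("all neurons excluded (zero baseline variance)")
    return pd.DataFrame.from_records(records).set_index("neuron_id")


def vector_matrix(vectors: pd.DataFrame) -> np.ndarray:
    """Extract the (n, 30) value matrix from a vector table."""
    cols = [f"v{i + 1:02d}" for i in range(30)]
    return vectors[cols].to_numpy(dtype=float)
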