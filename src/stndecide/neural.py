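"""Running-window firing rates and window-wise spike-count regressions.

Rates are computed in running windows aligned to motion or saccade onset,
with truncation rules that prevent leakage across events: motion-aligned
windows overlapping the last 100 ms before saccade onset are masked, and
saccade-aligned windows overlapping the first 200 ms after motion onset
are masked.

Two multiple linear regressions quantify task-related modulation of the
spike count in each window:

    count = b0 + bChoice * I_choice + bCohContra * I_cohC + bCohIpsi * I_cohI
    count = b0 + bChoice * I_choice + bRTContra * I_rtC + bRTIpsi * I_rtI

where I_choice is +1/-1 for contralateral/ipsilateral choices and the
one-sided coherence/RT regressors are zero on the other choice's trials.
Coefficient significance is a two-sided t-test at p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignedRates",
    "RegressionResult",
    "compute_running_rates",
    "zscore_rates",
    "regress_coherence",
    "regress_rt",
    "fraction_significant",
    "CHANCE_LEVEL",
]

#: Chance fraction of significant coefficients at the p < 0.05 criterion.
CHANCE_LEVEL = 0.05

#: Truncation margins (ms): motion-aligned activity is masked from 100 ms
#: before saccade onset; saccade-aligned activity before 200 ms after
#: motion onset.
PRE_SACCADE_TRUNCATION_MS = 100
POST_MOTION_TRUNCATION_MS = 200


@dataclass
class AlignedRates:
    """Window rates for a population, one alignment.

    ``rates``: (n_neurons, n_trials, n_windows) spikes/s.
    ``counts``: same shape, raw spike counts (regression response).
    ``valid``: same shape boolean; False where the truncation rules mask
    the window or the window was absent from the input table.
    """

    neuron_ids: list
    alignment: str
    window_centers_ms: np.ndarray
    window_ms: int
    trial_ids: np.ndarray
    rates: np.ndarray
    counts: np.ndarray
    valid: np.ndarray
    zscored: bool = False
    excluded_neurons: list = field(default_factory=list)

    def neuron_index(self, neuron_id) -> int:
        return self.neuron_ids.index(neuron_id)


def _truncation_mask(alignment, starts_ms, window_ms, rt_s):
    """valid[trial, window] under the alignment truncation rules."""
    rt_ms = rt_s * 1000.0
    starts = starts_ms[None, :]
    ends = starts + window_ms
    if alignment == "motion":
        # window must end before (saccade onset - 100 ms)
        return ends <= (rt_ms[:, None] - PRE_SACCADE_TRUNCATION_MS)
    if alignment == "saccade":
        # window start (relative to motion onset) must be at or after 200 ms
        return (rt_ms[:, None] + starts) >= POST_MOTION_TRUNCATION_MS
    raise ValueError(f"unknown alignment {alignment!r}")


def compute_running_rates(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    alignment: str,
    window_ms: int = 300,
    correct_only: bool = False,
) -> AlignedRates:
    """Pivot a spike-count table into per-window rates with truncation.

    ``spikes`` must carry columns ``neuron_id``, ``trial_id``,
    ``alignment``, ``window_start_ms``, ``window_ms``, ``count``; only
    rows matching ``alignment`` and ``window_ms`` are used.  Rates are
    count / window duration.
    """
    if alignment not in ("motion", "saccade"):
        raise ValueError(f"unknown alignment {alignment!r}")
    sel = spikes[
        (spikes["alignment"] == alignment) & (spikes["window_ms"] == window_ms)
    ]
    t = trials
    if correct_only:
        t = t[t["correct"]]
    trial_ids = t["trial_id"].to_numpy()
    sel = sel[sel["trial_id"].isin(set(trial_ids))]

    neuron_ids = sorted(sel["neuron_id"].unique())
    starts = np.sort(sel["window_start_ms"].unique())
    n_n, n_t, n_w = len(neuron_ids), len(trial_ids), len(starts)
    counts = np.zeros((n_n, n_t, n_w))
    present = np.zeros((n_n, n_t, n_w), dtype=bool)

    ni = {nid: i for i, nid in enumerate(neuron_ids)}
    ti = {tid: i for i, tid in enumerate(trial_ids)}
    wi = {s: i for i, s in enumerate(starts)}
    ii = sel["neuron_id"].map(ni).to_numpy()
    jj = sel["trial_id"].map(ti).to_numpy()
    kk = sel["window_start_ms"].map(wi).to_numpy()
    counts[ii, jj, kk] = sel["count"].to_numpy(dtype=float)
    present[ii, jj, kk] = True

    rt = t.set_index("trial_id").loc[trial_ids, "rt_s"].to_numpy(dtype=float)
    trunc = _truncation_mask(alignment, starts.astype(float), window_ms, rt)
    valid = present & trunc[None, :, :]
    rates = counts / (window_ms / 1000.0)
    return AlignedRates(
        neuron_ids=list(neuron_ids),
        alignment=alignment,
        window_centers_ms=starts.astype(float) + window_ms / 2.0,
        window_ms=window_ms,
        trial_ids=trial_ids,
        rates=rates,
        counts=counts,
        valid=valid,
    )


def zscore_rates(
    rates: AlignedRates,
    baseline_rates: AlignedRates,
    baseline_start_ms: float | None = None,
) -> AlignedRates:
    """z-score each neuron's rates by its baseline mean and SD.

    ``baseline_rates`` holds the baseline window (typically a single
    300 ms pre-motion or pre-target window); the per-neuron mean and SD
    are taken across trials.  Neurons with zero baseline variance are
    excluded and listed in ``excluded_neurons``.
    """
    if baseline_start_ms is not None:
        k = np.where(
            baseline_rates.window_centers_ms
            == baseline_start_ms + baseline_rates.window_ms / 2.0
        )[0]
        if len(k) == 0:
            raise ValueError("baseline window not present")
        base = baseline_rates.rates[:, :, k[0]]
    else:
        base = baseline_rates.rates[:, :, 0]

    keep, z, excluded = [], [], []
    for i, nid in enumerate(rates.neuron_ids):
        j = baseline_rates.neuron_ids.index(nid)
        mu = float(np.mean(base[j]))
        sd = float(np.std(base[j], ddof=1))
        if sd <= 0:
            excluded.append(nid)
            continue
        keep.append(i)
        z.append((rates.rates[i] - mu) / sd)
    return AlignedRates(
        neuron_ids=[rates.neuron_ids[i] for i in keep],
        alignment=rates.alignment,
        window_centers_ms=rates.window_centers_ms,
        window_ms=rates.window_ms,
        trial_ids=rates.trial_ids,
        rates=np.stack(z) if z else np.zeros((0,) + rates.rates.shape[1:]),
        counts=rates.counts[keep],
        valid=rates.valid[keep],
        zscored=True,
        excluded_neurons=excluded,
    )


@dataclass
class RegressionResult:
    """Window-wise regression coefficients for a population."""

    kind: str  # 'coherence' or 'rt'
    alignment: str
    neuron_ids: list
    window_centers_ms: np.ndarray
    coef_names: list
    # arrays of shape (n_neurons, n_windows, n_coefs)
    coefs: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    # (n_neurons, n_windows): False where the window was masked or the
    # design was rank-deficient
    fitted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, nid in enumerate(self.neuron_ids):
            for w, c in enumerate(self.window_centers_ms):
                if not self.fitted[i, w]:
                    continue
                for k, name in enumerate(self.coef_names):
                    rows.append(
                        {
                            "neuron_id": nid,
                            "alignment": self.alignment,
                            "window_center_ms": c,
                            "coef_name": name,
                            "estimate": self.coefs[i, w, k],
                            "t": self.t_values[i, w, k],
                            "p": self.p_values[i, w, k],
                        }
                    )
        return pd.DataFrame(rows)


def _design(kind: str, trials: pd.DataFrame, trial_ids: np.ndarray) -> np.ndarray:
    t = trials.set_index("trial_id").loc[trial_ids]
    contra = (t["choice"] == "contra").to_numpy()
    i_choice = np.where(contra, 1.0, -1.0)
    if kind == "coherence":
        mag = np.abs(t["signed_coh"].to_numpy(dtype=float))
        x_c = np.where(contra, mag, 0.0)
        x_i = np.where(~contra, mag, 0.0)
        names = ["b0", "bChoice", "bCohContra", "bCohIpsi"]
    elif kind == "rt":
        rt = t["rt_s"].to_numpy(dtype=float)
        x_c = np.where(contra, rt, 0.0)
        x_i = np.where(~contra, rt, 0.0)
        names = ["b0", "bChoice", "bRTContra", "bRTIpsi"]
    else:
        raise ValueError(kind)
    X = np.column_stack([np.ones_like(i_choice), i_choice, x_c, x_i])
    return X, names


def _regress(kind, rates: AlignedRates, trials: pd.DataFrame) -> RegressionResult:
    X_all, names = _design(kind, trials, rates.trial_ids)
    n_n, n_t, n_w = rates.counts.shape
    k = X_all.shape[1]
    coefs = np.full((n_n, n_w, k), np.nan)
    tvals = np.full((n_n, n_w, k), np.nan)
    pvals = np.full((n_n, n_w, k), np.nan)
    fitted = np.zeros((n_n, n_w), dtype=bool)

    # trial validity is shared across neurons (truncation depends only on
    # RT), so group neurons by their per-window valid-trial pattern
    for w in range(n_w):
        col_valid = rates.valid[:, :, w]
        patterns = {}
        for i in range(n_n):
            patterns.setdefault(col_valid[i].tobytes(), []).append(i)
        for key, idx in patterns.items():
            m = col_valid[idx[0]]
            n_obs = int(m.sum())
            if n_obs < k + 2:
                continue
            X = X_all[m]
            XtX = X.T @ X
            if np.linalg.matrix_rank(XtX) < k:
                continue
            XtX_inv = np.linalg.inv(XtX)
            Y = rates.counts[idx][:, m, w].T  # (n_obs, n_sub)
            B = XtX_inv @ (X.T @ Y)
            resid = Y - X @ B
            dof = n_obs - k
            s2 = np.sum(resid**2, axis=0) / dof
            se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
            with np.errstate(divide="ignore", invalid="ignore"):
                T = B / se
            P = 2.0 * stats.t.sf(np.abs(T), dof)
            coefs[idx, w, :] = B.T
            tvals[idx, w, :] = T.T
            pvals[idx, w, :] = P.T
            fitted[idx, w] = True

    return RegressionResult(
        kind=kind,
        alignment=rates.alignment,
        neuron_ids=list(rates.neuron_ids),
        window_centers_ms=rates.window_centers_ms,
        coef_names=names,
        coefs=coefs,
        t_values=tvals,
        p_values=pvals,
        fitted=fitted,
    )


def regress_coherence(rates: AlignedRates, trials: pd.DataFrame) -> RegressionResult:
    """Window-wise OLS of spike count on choice and one-sided coherence."""
    return _regress("coherence", rates, trials)


def regress_rt(rates: AlignedRates, trials: pd.DataFrame) -> RegressionResult:
    """Window-wise OLS of spike count on choice and one-sided RT."""
    return _regress("rt", rates, trials)


def fraction_significant(
    result: RegressionResult,
    coef_name: str,
    alpha: float = 0.05,
    selective_only: bool | None = None,
) -> pd.DataFrame:
    """Per-window fraction of neurons with a significant coefficient.

    ``selective_only=True`` restricts to neurons whose ``bChoice`` is
    significant at that window; ``False`` restricts to non-selective
    neurons; ``None`` uses all fitted neurons.  Windows with an empty
    stratum report NaN.  The output includes the chance level column.
    """
    k = result.coef_names.index(coef_name)
    kc = result.coef_names.index("bChoice")
    rows = []
    for w, c in enumerate(result.window_centers_ms):
        m = result.fitted[:, w]
        if selective_only is not None:
            sel = result.p_values[:, w, kc] < alpha
            m = m & (sel if selective_only else ~sel)
        n = int(m.sum())
        frac = float(np.mean(result.p_values[m, w, k] < alpha)) if n else np.nan
        rows.append(
            {
                "window_center_ms": c,
                "coef_name": coef_name,
                "fraction": frac,
                "n_neurons": n,
                "chance_level": CHANCE_LEVEL,
            }
        )
    return pd.DataFrame(rows)
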