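"""Synthetic neural populations from cluster template profiles.

Four template families parameterize the qualitatively distinct
task-related firing patterns of STN subpopulations:

1. choice- and coherence-dependent activity that ramps up during motion
   viewing (pooling/normalization-style signal);
2. an early, sharp, choice- and coherence-independent rise that decays
   toward saccade onset (early-brake signal);
3. coherence-dependent ramping shared by both choices, with a
   choice-selective burst just before the saccade (gating-style signal);
4. weak, mixed task-related modulation.

Each neuron gets a log-normal multiplicative gain on its modulation and
additive Gaussian jitter per (coherence, epoch) cell, shared across the
two choices so that choice-independence of templates 2-4 during motion
viewing is preserved exactly in expectation structure.  Spike counts are
Poisson draws from a piecewise-linear rate profile through the epoch
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTemplate",
    "generate_neuron_templates",
    "generate_null_templates",
    "sample_spike_counts",
    "generate_recording_dataset",
    "EPOCH_WINDOWS",
    "BASELINE_WINDOW",
    "CANONICAL_WINDOWS",
]

#: Analysis epochs: (alignment, start_ms, width_ms).
EPOCH_WINDOWS = {
    "early": ("motion", 100, 200),
    "late": ("motion", 300, 200),
    "peri_saccade": ("saccade", -100, 200),
}

#: Pre-motion baseline window used for z-scoring activity vectors.
BASELINE_WINDOW = ("motion", -300, 300)

#: Windows sampled by default: the three epochs plus the baseline.
CANONICAL_WINDOWS = [BASELINE_WINDOW] + list(EPOCH_WINDOWS.values())

#: Normalized coherence levels used inside template shapes.
_U = np.array([0.032, 0.064, 0.128, 0.256, 0.512]) / 0.512


def _modulation(cluster_id: int) -> np.ndarray:
    """Mean rate modulation (spikes/s above baseline), shape (2, 5, 3).

    Axis 0 is (preferred, other) choice, axis 1 coherence ascending,
    axis 2 epoch (early, late, peri-saccade).
    """
    m = np.zeros((2, 5, 3))
    u = _U
    if cluster_id == 1:
        m[0, :, 0] = 3.0 + 6.0 * u
        m[0, :, 1] = 7.0 + 10.0 * u
        m[0, :, 2] = 16.0
        m[1, :, 0] = 1.0 - 1.5 * u
        m[1, :, 1] = 1.0 - 3.0 * u
        m[1, :, 2] = 6.0
    elif cluster_id == 2:
        m[:, :, 0] = 14.0
        m[:, :, 1] = 7.0
        m[:, :, 2] = 1.0
    elif cluster_id == 3:
        m[:, :, 0] = 2.0 + 4.0 * u
        m[:, :, 1] = 5.0 + 9.0 * u
        m[0, :, 2] = 13.0
        m[1, :, 2] = 4.0
    elif cluster_id == 4:
        # weak, mixed modulation: a low-amplitude pattern taken from the
        # arbitrary (orthogonalized) seed shape, so it resembles none of
        # the three theorized patterns
        from stndecide.cluster.seeds import make_model_seeds

        s4 = make_model_seeds().vectors[3].reshape(3, 2, 5)  # epoch, choice, coh
        # choice-symmetrized so the pattern is invariant to the
        # preferred/other relabeling applied when vectors are built
        sym = s4.mean(axis=1, keepdims=True)
        m[:] = 8.0 * np.transpose(np.broadcast_to(sym, s4.shape), (1, 2, 0))
    else:
        raise ValueError(f"cluster_id must be in {{1, 2, 3, 4}}, got {cluster_id}")
    return m


@dataclass
class NeuronTemplate:
    """Ground-truth rate template for one synthetic neuron.

    ``rates`` has shape (2 choices [contra, ipsi], 5 coherences ascending,
    3 epochs [early, late, peri-saccade]) in spikes/s.
    """

    neuron_id: str
    true_cluster: int
    baseline_rate: float
    rates: np.ndarray
    pref_side: str  # which physical side carries the 'preferred' pattern
    location: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (2, 5, 3):
            raise ValueError("rates must have shape (2, 5, 3)")
        if np.any(self.rates < 0) or self.baseline_rate < 0:
            raise ValueError("rates must be non-negative")

    def epoch_rate(self, choice: str, coh_idx: int, epoch_idx: int) -> float:
        c = 0 if choice == "contra" else 1
        return float(self.rates[c, coh_idx, epoch_idx])

    def to_dict(self) -> dict:
        return {
            "neuron_id": self.neuron_id,
            "true_cluster": self.true_cluster,
            "baseline_rate": self.baseline_rate,
            "rates": self.rates.tolist(),
            "pref_side": self.pref_side,
            "location": np.asarray(self.location).tolist(),
        }


def generate_neuron_templates(
    cluster_id: int,
    n: int,
    seed: int = 0,
    separation: float = 1.0,
    gain_sd: float = 0.3,
    jitter_sd: float = 0.6,
    baseline_median: float = 12.0,
    baseline_sigma: float = 0.6,
    id_prefix: str | None = None,
) -> list:
    """Generate ``n`` templates of one cluster family.

    ``separation`` scales the mean modulation relative to the jitter
    (1.0 = default study conditions; 0.5 = half separation).  ``jitter_sd``
    is the SD (spikes/s) of the per-(coherence, epoch) additive jitter,
    shared across choices.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    base_mod = _modulation(cluster_id)
    prefix = id_prefix or f"c{cluster_id}"
    out = []
    for i in range(n):
        baseline = float(
            np.exp(rng.normal(np.log(baseline_median), baseline_sigma))
        )
        gain = float(np.exp(rng.normal(0.0, gain_sd))) if gain_sd > 0 else 1.0
        jitter = rng.normal(0.0, jitter_sd, size=(1, 5, 3)) if jitter_sd > 0 else 0.0
        mod = separation * gain * base_mod + jitter  # jitter broadcast over choices
        pref_side = "contra" if rng.random() < 0.5 else "ipsi"
        rates_po = np.maximum(baseline + mod, 0.0)  # (pref, other) order
        rates = rates_po if pref_side == "contra" else rates_po[::-1]
        loc = np.array(
            [rng.uniform(0.0, 4.0), rng.uniform(0.0, 4.0), rng.uniform(0.0, 5.0)]
        )
        out.append(
            NeuronTemplate(
                neuron_id=f"{prefix}_{i:03d}",
                true_cluster=cluster_id,
                baseline_rate=baseline,
                rates=rates,
                pref_side=pref_side,
                location=loc,
            )
        )
    return out


def generate_null_templates(n: int, seed: int = 0, baseline_median: float = 12.0,
                            baseline_sigma: float = 0.6) -> list:
    """Templates with no task-related modulation (type-I calibration)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        baseline = float(np.exp(rng.normal(np.log(baseline_median), baseline_sigma)))
        out.append(
            NeuronTemplate(
                neuron_id=f"null_{i:04d}",
                true_cluster=4,
                baseline_rate=baseline,
                rates=np.full((2, 5, 3), baseline),
                pref_side="contra",
                location=rng.uniform(0.0, 4.0, size=3),
            )
        )
    return out


def _profile_rate(template: NeuronTemplate, choice_idx: int, coh_idx: int,
                  t: np.ndarray, rt: np.ndarray) -> np.ndarray:
    """Piecewise-linear rate (spikes/s) at times ``t`` from motion onset."""
    base = template.baseline_rate
    r1, r2, r3 = template.rates[choice_idx, coh_idx, :]
    n = len(t)
    xs = np.empty((n, 8))
    xs[:, 0] = 0.05
    xs[:, 1] = 0.10
    xs[:, 2] = 0.30
    xs[:, 3] = 0.35
    xs[:, 4] = 0.50
    xs[:, 5] = rt - 0.10
    xs[:, 6] = rt + 0.10
    xs[:, 7] = rt + 0.25
    xs = np.maximum.accumulate(xs + np.arange(8) * 1e-6, axis=1)
    ys = np.array([base, r1, r1, r2, r2, r3, r3, base])
    out = np.empty(n)
    for i in range(n):
        out[i] = np.interp(t[i], xs[i], ys, left=base, right=base)
    return out


def _window_mean_rate(template, choice_idx, coh_idx, start_s, width_s,
                      alignment, rt):
    """Mean profile rate over a window, for all trials at once."""
    offsets = (np.arange(5) + 0.5) / 5.0 * width_s + start_s
    acc = np.zeros(len(rt))
    for off in offsets:
        t = np.full(len(rt), off) if alignment == "motion" else rt + off
        acc += _profile_rate(template, choice_idx, coh_idx, t, rt)
    return acc / len(offsets)


def sample_spike_counts(
    templates: list,
    trials: pd.DataFrame,
    windows=None,
    seed: int = 0,
    coherences=None,
) -> pd.DataFrame:
    """Poisson spike counts per neuron, trial, and analysis window.

    ``windows`` is a list of ``(alignment, start_ms, width_ms)`` tuples
    (default: the three epochs plus the pre-motion baseline).  Returns a
    table with columns ``neuron_id``, ``trial_id``, ``alignment``,
    ``window_start_ms``, ``window_ms``, ``count``.  Deterministic given
    ``seed``.
    """
    if windows is None:
        windows = CANONICAL_WINDOWS
    for _, _, width in windows:
        if width <= 0:
            raise ValueError("window width must be > 0")
    if coherences is None:
        mags = np.sort(np.unique(np.abs(trials["signed_coh"].to_numpy())))
    else:
        mags = np.sort(np.asarray(list(coherences), dtype=float))
    rng = np.random.default_rng(seed)

    rt = trials["rt_s"].to_numpy(dtype=float)
    choice_idx = np.where(trials["choice"].to_numpy() == "contra", 0, 1)
    coh_idx = np.searchsorted(mags, np.abs(trials["signed_coh"].to_numpy()) - 1e-12)
    coh_idx = np.clip(coh_idx, 0, len(mags) - 1)
    trial_ids = trials["trial_id"].to_numpy()
    n_trials = len(trials)

    frames = []
    for tpl in templates:
        for alignment, start_ms, width_ms in windows:
            start_s, width_s = start_ms / 1000.0, width_ms / 1000.0
            rates = np.empty(n_trials)
            for c in (0, 1):
                for j in range(len(mags)):
                    m = (choice_idx == c) & (coh_idx == j)
                    if not m.any():
                        continue
                    rates[m] = _window_mean_rate(
                        tpl, c, j, start_s, width_s, alignment, rt[m]
                    )
            counts = rng.poisson(np.maximum(rates, 0.0) * width_s)
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": tpl.neuron_id,
                        "trial_id": trial_ids,
                        "alignment": alignment,
                        "window_start_ms": start_ms,
                        "window_ms": width_ms,
                        "count": counts,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_recording_dataset(
    n_per_cluster: int,
    trials_per_cond: int = 30,
    seed: int = 0,
    separation: float = 1.0,
    windows=None,
    params=None,
):
    """Labeled synthetic population with session-like trial structure.

    Returns ``(spikes, trials, templates)``: a spike-count table over the
    requested windows, the behavioral trial table shared by all neurons,
    and the ground-truth templates (4 clusters x ``n_per_cluster``).
    """
    from stndecide.ddm.params import DDMParams
    from stndecide.synth.behavior import simulate_ddm_trials

    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    if params is None:
        # slower parameter regime so epochs rarely overlap within a trial
        params = DDMParams(
            a=1.3, b_collapse=1.0, b_t=0.4, k=6.0, t0_contra=0.35, t0_ipsi=0.35
        )
    rng = np.random.default_rng(seed)
    trials = simulate_ddm_trials(
        params, None, n_per_cond=trials_per_cond,
        seed=int(rng.integers(2**31 - 1)), session_id="recording",
    )
    templates = []
    for cid in (1, 2, 3, 4):
        templates.extend(
            generate_neuron_templates(
                cid, n_per_cluster, seed=int(rng.integers(2**31 - 1)),
                separation=separation,
            )
        )
    spikes = sample_spike_counts(
        templates, trials, windows=windows, seed=int(rng.integers(2**31 - 1))
    )
    return spikes, trials, templates
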