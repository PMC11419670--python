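"""Synthetic behavioral sessions from the collapsing-bound DDM.

Trials are simulated by Euler-Maruyama integration of the decision
variable to absorption at the collapsing bounds.  Stimulated trials use
base parameters plus the additive microstimulation deltas and are
interleaved 1:1 with control trials.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stndecide.ddm._kernels import simulate_paths
from stndecide.ddm.params import DDMEffect, DDMParams

__all__ = ["DEFAULT_COHERENCES", "simulate_ddm_trials"]

#: Canonical five-level coherence ladder (proportion of coherent dots).
DEFAULT_COHERENCES = (0.032, 0.064, 0.128, 0.256, 0.512)

#: Simulation step (s), horizon (s) and resampling cap for non-absorption.
SIM_DT = 5e-4
SIM_T_MAX = 10.0
RETRY_CAP = 5


def _simulate_condition(p: DDMParams, signed_coh: float, n: int, seed: int):
    v = p.k * (signed_coh + p.me)
    choices, dts = simulate_paths(
        n, v, p.a, p.b_collapse, p.b_t, p.z, p.sigma, SIM_DT, SIM_T_MAX, seed
    )
    for attempt in range(RETRY_CAP):
        bad = choices == 0
        if not bad.any():
            break
        c2, t2 = simulate_paths(
            int(bad.sum()), v, p.a, p.b_collapse, p.b_t, p.z, p.sigma,
            SIM_DT, SIM_T_MAX, seed + 1 + attempt,
        )
        choices[bad] = c2
        dts[bad] = t2
    if (choices == 0).any():
        raise RuntimeError(
            f"{int((choices == 0).sum())} paths not absorbed within "
            f"{SIM_T_MAX} s after {RETRY_CAP} retries (signed_coh={signed_coh}); "
            "parameters are likely pathological"
        )
    return choices, dts


def simulate_ddm_trials(
    params: DDMParams,
    effect: DDMEffect | None = None,
    coherences=DEFAULT_COHERENCES,
    n_per_cond: int = 50,
    seed: int = 0,
    session_id: str = "synthetic",
) -> pd.DataFrame:
    """Simulate one session's trial table.

    ``n_per_cond`` trials are generated for every combination of signed
    coherence (both directions of each of the five magnitudes) and
    stimulation status, giving ``20 * n_per_cond`` trials interleaved in a
    deterministic shuffled order.  Columns: ``session_id``, ``trial_id``,
    ``signed_coh`` (positive toward the contralateral target), ``estim``,
    ``choice`` (``contra``/``ipsi``), ``rt_s``, ``decision_time_s``
    (ground truth), ``correct``.
    """
    if n_per_cond < 1:
        raise ValueError("n_per_cond must be >= 1")
    mags = sorted(float(c) for c in coherences)
    if len(set(mags)) != 5:
        raise ValueError("exactly 5 distinct coherence magnitudes required")
    if effect is not None and not effect.shift_is_valid(params):
        raise ValueError("params + effect violate DDM parameter invariants")

    rng = np.random.default_rng(seed)
    rows = []
    for estim in (False, True):
        p = params.with_effect(effect) if estim else params
        for mag in mags:
            for sign in (1.0, -1.0):
                coh = sign * mag
                sub_seed = int(rng.integers(2**31 - 1000))
                choices, dts = _simulate_condition(p, coh, n_per_cond, sub_seed)
                contra = choices == 1
                rt = dts + np.where(contra, p.t0_contra, p.t0_ipsi)
                correct = np.sign(choices) == np.sign(coh) if coh != 0 else (
                    rng.random(n_per_cond) < 0.5
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "signed_coh": coh,
                            "estim": estim,
                            "choice": np.where(contra, "contra", "ipsi"),
                            "rt_s": rt,
                            "decision_time_s": dts,
                            "correct": correct,
                        }
                    )
                )
    out = pd.concat(rows, ignore_index=True)
    order = rng.permutation(len(out))
    out = out.iloc[order].reset_index(drop=True)
    out.insert(0, "trial_id", np.arange(len(out)))
    out.insert(0, "session_id", session_id)
    return out
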