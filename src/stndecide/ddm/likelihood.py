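"""Joint choice + RT likelihood of a session under the collapsing-bound DDM.

Each trial contributes the defective first-passage density of its choice,
evaluated at its decision time (RT minus the choice-matched non-decision
time).  Densities are solved once per (stimulation status, signed
coherence) condition and cached within a call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stndecide.ddm._kernels import fpt_kernel
from stndecide.ddm.fpt import GridConfig
from stndecide.ddm.params import DDMEffect, DDMParams

__all__ = ["session_loglik", "LIKELIHOOD_FLOOR"]

#: Per-trial likelihood floor (1/s).  Trials whose RT is below the fitted
#: non-decision time, or beyond the solver horizon, contribute this floor
#: instead of raising, which keeps the objective finite for optimizers.
LIKELIHOOD_FLOOR = 1e-10


def _condition_density(
    p: DDMParams, coh: float, grid: GridConfig, t_max: float, cache: dict | None
):
    v = p.k * (coh + p.me)
    nt = max(int(np.ceil(t_max / grid.dt)), 8)
    key = (round(v, 12), p.a, p.b_collapse, p.b_t, p.z, p.sigma, nt)
    if cache is not None and key in cache:
        return cache[key]
    g_up, g_lo, _ = fpt_kernel(
        v, p.a, p.b_collapse, p.b_t, p.z, p.sigma, grid.dt, grid.nx, nt
    )
    if cache is not None:
        cache[key] = (g_up, g_lo)
    return g_up, g_lo


def session_loglik(
    trials: pd.DataFrame,
    params: DDMParams,
    effect: DDMEffect | None = None,
    grid: GridConfig | None = None,
    return_diagnostics: bool = False,
    cache: dict | None = None,
):
    """Sum of per-trial log densities for one session's trial table.

    ``trials`` needs columns ``signed_coh``, ``estim``, ``choice``
    (``contra``/``ipsi``) and ``rt_s``.  Invalid parameter combinations
    return ``-inf`` (with a diagnostic when requested) rather than raising.
    ``cache`` (an optional dict) memoizes condition densities across
    calls with partially overlapping parameters, which speeds up
    finite-difference gradients during fitting.
    """
    if grid is None:
        grid = GridConfig()
    diag = {"n_floored": 0, "invalid_params": False}
    if len(trials) == 0:
        return (0.0, diag) if return_diagnostics else 0.0

    if not params.is_valid() or (effect is not None and not effect.shift_is_valid(params)):
        diag["invalid_params"] = True
        out = -np.inf
        return (out, diag) if return_diagnostics else out

    total = 0.0
    estim_col = trials["estim"].to_numpy(dtype=bool)
    coh_col = trials["signed_coh"].to_numpy(dtype=float)
    rt_col = trials["rt_s"].to_numpy(dtype=float)
    is_contra = (trials["choice"].to_numpy() == "contra")

    for flag, p in ((False, params), (True, params.with_effect(effect or DDMEffect.zero()))):
        sel = estim_col == flag
        if not sel.any():
            continue
        rt = rt_col[sel]
        contra = is_contra[sel]
        coh = coh_col[sel]
        rt_dec = rt - np.where(contra, p.t0_contra, p.t0_ipsi)
        t_need = float(np.max(rt_dec, initial=0.0)) + 2 * grid.dt
        t_max = min(grid.t_max, max(t_need, 10 * grid.dt))
        t_grid = (np.arange(max(int(np.ceil(t_max / grid.dt)), 8)) + 1) * grid.dt
        if cache is not None and len(cache) > 20000:
            cache.clear()
        for c in np.unique(coh):
            g_up, g_lo = _condition_density(p, float(c), grid, t_max, cache)
            if not (np.isfinite(g_up).all() and np.isfinite(g_lo).all()):
                diag["invalid_params"] = True
                out = -np.inf
                return (out, diag) if return_diagnostics else out
            m = coh == c
            for side, g in ((contra & m, g_up), (~contra & m, g_lo)):
                if not side.any():
                    continue
                dens = np.interp(rt_dec[side], t_grid, g, left=0.0, right=0.0)
                diag["n_floored"] += int(np.sum(dens < LIKELIHOOD_FLOOR))
                total += float(np.sum(np.log(np.maximum(dens, LIKELIHOOD_FLOOR))))

    return (total, diag) if return_diagnostics else total
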