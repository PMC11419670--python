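"""MAP fitting of the collapsing-bound DDM and AIC model comparison.

Each variant is fit by maximizing log-likelihood + log-prior over the
eight base parameters and the variant's free microstimulation deltas.
Five runs are performed per fit from independent prior-drawn starts
(optionally one start is replaced by a warm start from a nested fit);
each run is a short bounded quasi-Newton exploration and the best run is
then polished to convergence.  AIC uses the log-likelihood component at
the MAP point.

Weakly-informative priors keep the weakly identified directions of the
collapsing-bound likelihood surface (bound height vs collapse speed vs
non-decision time) anchored, which is the usual motivation for MAP over
plain maximum likelihood in this model family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from stndecide.ddm._kernels import fpt_kernel, interp_loglik
from stndecide.ddm.fpt import COMPARE_GRID, FIT_GRID, GridConfig
from stndecide.ddm.likelihood import LIKELIHOOD_FLOOR, session_loglik
from stndecide.ddm.params import (
    GROUP_TO_REDUCED,
    PARAM_NAMES,
    DDMEffect,
    DDMParams,
    VariantSpec,
    VARIANTS,
)

__all__ = ["ParamPrior", "default_prior", "DDMFit", "fit_map", "compare_models", "aic"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def aic(loglik: float, n_free: int) -> float:
    """Akaike information criterion, 2 * n_free - 2 * loglik."""
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    return 2.0 * n_free - 2.0 * loglik


@dataclass(frozen=True)
class ParamPrior:
    """Prior for one scalar parameter.

    ``kind`` is one of ``normal`` (args: mu, sd), ``lognormal``
    (args: log-median, sd of log), ``halfnormal`` (args: scale),
    ``uniform`` (args: lo, hi), ``truncnormal`` (args: mu, sd; truncated
    to [lo, hi]).  ``lo``/``hi`` double as optimizer box bounds and
    ``scale`` normalizes the optimizer space.
    """

    kind: str
    args: tuple
    lo: float
    hi: float
    scale: float

    def logpdf(self, x: float) -> float:
        if self.kind == "normal":
            mu, sd = self.args
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
        if self.kind == "lognormal":
            logm, s = self.args
            if x <= 0:
                return -np.inf
            lx = math.log(x)
            return -0.5 * ((lx - logm) / s) ** 2 - lx - math.log(s) - _LOG_SQRT_2PI
        if self.kind == "halfnormal":
            (s,) = self.args
            if x < 0:
                return -np.inf
            return 0.5 * math.log(2.0 / math.pi) - math.log(s) - 0.5 * (x / s) ** 2
        if self.kind == "uniform":
            lo, hi = self.args
            return -math.log(hi - lo) if lo <= x <= hi else -np.inf
        if self.kind == "truncnormal":
            mu, sd = self.args
            if not (self.lo <= x <= self.hi):
                return -np.inf
            # normalization constant omitted (additive, parameter-independent)
            return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
        raise ValueError(self.kind)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "normal":
            mu, sd = self.args
            x = rng.normal(mu, sd)
        elif self.kind == "lognormal":
            logm, s = self.args
            x = math.exp(rng.normal(logm, s))
        elif self.kind == "halfnormal":
            (s,) = self.args
            x = abs(rng.normal(0.0, s))
        elif self.kind == "uniform":
            lo, hi = self.args
            x = rng.uniform(lo, hi)
        elif self.kind == "truncnormal":
            mu, sd = self.args
            x = rng.normal(mu, sd)
        else:
            raise ValueError(self.kind)
        return float(np.clip(x, self.lo + 1e-9, self.hi - 1e-9))


def default_prior() -> dict:
    """Weakly-informative priors for the 8 base parameters and 8 deltas.

    Log-normal on the positive scale parameters (a, k), half-normal on
    the collapse speed, uniform on the collapse onset over [0, 2] s,
    truncated normal on the non-decision times, and zero-centered normals
    on the bias terms and all microstimulation deltas.
    """
    return {
        "a": ParamPrior("lognormal", (0.0, 0.5), 0.35, 4.0, 0.3),
        "b_collapse": ParamPrior("halfnormal", (1.0,), 0.0, 8.0, 0.5),
        "b_t": ParamPrior("uniform", (0.0, 2.0), 0.0, 2.0, 0.3),
        "k": ParamPrior("lognormal", (math.log(6.0), 0.6), 0.5, 40.0, 2.0),
        "me": ParamPrior("normal", (0.0, 0.2), -0.6, 0.6, 0.05),
        "z": ParamPrior("normal", (0.0, 0.2), -0.6, 0.6, 0.05),
        "t0_contra": ParamPrior("truncnormal", (0.3, 0.12), 0.08, 0.8, 0.05),
        "t0_ipsi": ParamPrior("truncnormal", (0.3, 0.12), 0.08, 0.8, 0.05),
        "d_a": ParamPrior("normal", (0.0, 0.3), -1.5, 1.5, 0.1),
        "d_b_collapse": ParamPrior("normal", (0.0, 1.0), -6.0, 6.0, 0.5),
        "d_b_t": ParamPrior("normal", (0.0, 0.3), -1.5, 1.5, 0.1),
        "d_k": ParamPrior("normal", (0.0, 3.0), -20.0, 20.0, 1.0),
        "d_me": ParamPrior("normal", (0.0, 0.1), -0.5, 0.5, 0.05),
        "d_z": ParamPrior("normal", (0.0, 0.15), -0.6, 0.6, 0.05),
        "d_t0_contra": ParamPrior("normal", (0.0, 0.08), -0.4, 0.4, 0.03),
        "d_t0_ipsi": ParamPrior("normal", (0.0, 0.08), -0.4, 0.4, 0.03),
    }


@dataclass
class DDMFit:
    """Result of one MAP fit."""

    variant: VariantSpec
    params: DDMParams
    effect: DDMEffect
    loglik: float
    logpost: float
    aic: float
    n_free_params: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.name,
            "params": self.params.as_dict(),
            "effect": self.effect.as_dict(),
            "loglik": self.loglik,
            "logpost": self.logpost,
            "aic": self.aic,
            "n_free_params": self.n_free_params,
            "diagnostics": dict(self.diagnostics),
        }


def _free_names(variant: VariantSpec) -> list:
    return list(PARAM_NAMES) + ["d_" + n for n in variant.free_param_names]


class _SessionObjective:
    """Negative log-posterior with per-condition caching of FPT solves.

    Trial data are unpacked to numpy arrays once; finite-difference
    gradients then reuse cached condition densities for parameters that
    do not alter the diffusion (non-decision times) or that alter only
    one stimulation arm (the deltas).
    """

    def __init__(self, trials, names, prior, grid, cache=None):
        self.names = names
        self.prior = [prior[n] for n in names]
        self.grid = grid
        self.cache = {} if cache is None else cache
        self.n_idx = {n: i for i, n in enumerate(names)}

        estim = trials["estim"].to_numpy(dtype=bool)
        coh = trials["signed_coh"].to_numpy(dtype=float)
        rt = trials["rt_s"].to_numpy(dtype=float)
        contra = trials["choice"].to_numpy() == "contra"
        self.conds = []
        for flag in (False, True):
            m0 = estim == flag
            for c in np.unique(coh[m0]):
                m = m0 & (coh == c)
                self.conds.append(
                    (flag, float(c), rt[m & contra], rt[m & ~contra])
                )
        self.nt = max(int(np.ceil(rt.max() / grid.dt)), 8)
        self.t_grid = (np.arange(self.nt) + 1) * grid.dt

    def _get(self, name, x, default=0.0):
        i = self.n_idx.get(name)
        return x[i] if i is not None else default

    def loglik(self, x: np.ndarray) -> float:
        g = self.grid
        base = {n: x[i] for i, n in enumerate(PARAM_NAMES)}
        total = 0.0
        for flag, c, rt_con, rt_ips in self.conds:
            if flag:
                p = {n: base[n] + self._get("d_" + n, x) for n in PARAM_NAMES}
            else:
                p = base
            v = p["k"] * (c + p["me"])
            key = (v, p["a"], p["b_collapse"], p["b_t"], p["z"], g.dt, g.nx, self.nt)
            hit = self.cache.get(key)
            if hit is None:
                g_up, g_lo, _ = fpt_kernel(
                    v, p["a"], p["b_collapse"], p["b_t"], p["z"], 1.0,
                    g.dt, g.nx, self.nt,
                )
                if len(self.cache) > 20000:
                    self.cache.clear()
                self.cache[key] = (g_up, g_lo)
            else:
                g_up, g_lo = hit
            if len(rt_con):
                total += interp_loglik(
                    rt_con, p["t0_contra"], g.dt, g_up, LIKELIHOOD_FLOOR
                )
            if len(rt_ips):
                total += interp_loglik(
                    rt_ips, p["t0_ipsi"], g.dt, g_lo, LIKELIHOOD_FLOOR
                )
        return total

    def validity_penalty(self, x: np.ndarray) -> float:
        a = x[0]
        z = self._get("z", x)
        a_s = a + self._get("d_a", x)
        z_s = z + self._get("d_z", x)
        pen = 0.0
        for margin in (
            a - abs(z) - 1e-3,
            a_s - abs(z_s) - 1e-3,
            a_s - 1e-3,
            x[1] + self._get("d_b_collapse", x),
            x[2] + self._get("d_b_t", x),
            x[6] + self._get("d_t0_contra", x),
            x[7] + self._get("d_t0_ipsi", x),
        ):
            if margin < 0:
                pen += 1e4 * (1.0 + margin * margin)
        return pen

    def logprior(self, x: np.ndarray) -> float:
        return sum(pr.logpdf(v) for pr, v in zip(self.prior, x))

    def __call__(self, xs: np.ndarray, scale: np.ndarray) -> float:
        x = xs * scale
        pen = self.validity_penalty(x)
        if pen > 0:
            return 1e8 + pen
        ll = self.loglik(x)
        if not np.isfinite(ll):
            return 1e8
        lp = ll + self.logprior(x)
        if not np.isfinite(lp):
            return 1e8
        return -lp


def _unpack(x: np.ndarray, names: list):
    base = {n: x[i] for i, n in enumerate(PARAM_NAMES)}
    deltas = {names[i]: x[i] for i in range(len(PARAM_NAMES), len(names))}
    params = DDMParams(**base)
    effect = DDMEffect(**deltas)
    return params, effect


def fit_map(
    trials: pd.DataFrame,
    variant: VariantSpec | str,
    seed: int,
    grid: GridConfig | None = None,
    prior: dict | None = None,
    n_starts: int = 5,
    warm_start: dict | None = None,
    stage1_maxiter: int = 8,
    stage2_maxiter: int = 80,
    cache: dict | None = None,
) -> DDMFit:
    """Maximum a posteriori fit of one variant to one session.

    ``warm_start`` (a mapping of parameter name to value) replaces one of
    the ``n_starts`` prior-drawn starting points; the total number of
    runs is unchanged.  Deterministic given ``seed``.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if grid is None:
        grid = FIT_GRID
    if prior is None:
        prior = default_prior()
    if trials["signed_coh"].nunique() < 2:
        raise ValueError("need at least 2 coherence levels to fit")
    if trials["choice"].nunique() < 2:
        raise ValueError("need both choices present to fit")

    names = _free_names(variant)
    obj = _SessionObjective(trials, names, prior, grid, cache=cache)
    lo = np.array([prior[n].lo for n in names])
    hi = np.array([prior[n].hi for n in names])
    scale = np.array([prior[n].scale for n in names])

    rng = np.random.default_rng(seed)
    starts = []
    for _ in range(n_starts):
        for _attempt in range(100):
            x0 = np.array([prior[n].sample(rng) for n in names])
            if obj.validity_penalty(x0) == 0.0:
                break
        starts.append(x0)
    if warm_start is not None:
        x0 = np.array([warm_start.get(n, 0.0) for n in names])
        starts[0] = np.clip(x0, lo + 1e-9, hi - 1e-9)

    bounds = list(zip(lo / scale, hi / scale))
    stage1 = []
    for x0 in starts:
        res = optimize.minimize(
            obj, x0 / scale, args=(scale,),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": stage1_maxiter, "eps": 1e-3, "ftol": 1e-9},
        )
        stage1.append(res)
    run_logposts = [-r.fun for r in stage1]
    best_idx = int(np.argmax(run_logposts))
    res = optimize.minimize(
        obj, stage1[best_idx].x, args=(scale,),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": stage2_maxiter, "eps": 1e-3, "ftol": 1e-10},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e8:
        raise RuntimeError(
            f"all {n_starts} runs failed to reach a valid optimum for variant "
            f"{variant.name}; per-run log-posteriors: {run_logposts}"
        )
    x = res.x * scale
    params, effect = _unpack(x, names)
    effect = effect.masked(variant.free_groups)
    ll = obj.loglik(x)
    return DDMFit(
        variant=variant,
        params=params,
        effect=effect,
        loglik=float(ll),
        logpost=float(ll + obj.logprior(x)),
        aic=aic(ll, variant.n_free_params),
        n_free_params=variant.n_free_params,
        diagnostics={
            "run_logposts": run_logposts,
            "best_run": best_idx,
            "n_iter_polish": int(res.nit),
            "converged": bool(res.success),
        },
    )


def _fit_dict(fit: DDMFit) -> dict:
    d = {n: getattr(fit.params, n) for n in PARAM_NAMES}
    d.update({"d_" + n: getattr(fit.effect, "d_" + n) for n in PARAM_NAMES})
    return d


def compare_models(
    trials: pd.DataFrame,
    seed: int,
    grid: GridConfig | None = None,
    prior: dict | None = None,
    delta_aic: float = 3.0,
    **fit_kwargs,
) -> dict:
    """Fit all eight variants and apply the delta-AIC > 3 selection rule.

    Returns a dict with the eight fits, a flat comparison table, the
    session-level effect flag (AIC_None - AIC_Full > 3), and per-group
    flags requiring *both* AIC_NoX - AIC_Full > 3 and the session flag.
    Reduced variants are warm-started from the Full fit (with the fixed
    group's deltas zeroed) as one of their five runs, which also keeps
    the fitted log-likelihoods consistent with variant nesting.  All
    eight fits share the comparison grid (coarser than the single-fit
    default, so the grid bias cancels in AIC differences) and one solve
    cache.
    """
    if grid is None:
        grid = COMPARE_GRID
    rng = np.random.default_rng(seed)
    sub = {name: int(rng.integers(2**31 - 1)) for name in VARIANTS}
    fit_kwargs = dict(fit_kwargs)
    fit_kwargs.setdefault("cache", {})
    # comparison budget: warm-start chaining makes long polishing
    # unnecessary; AIC margins of interest are > 3 while these budgets
    # leave residuals well below 1
    fit_kwargs.setdefault("stage1_maxiter", 4)
    fit_kwargs.setdefault("stage2_maxiter", 30)

    fits = {}
    fits["None"] = fit_map(trials, "None", sub["None"], grid=grid, prior=prior, **fit_kwargs)
    fits["Full"] = fit_map(
        trials, "Full", sub["Full"], grid=grid, prior=prior,
        warm_start=_fit_dict(fits["None"]), **fit_kwargs,
    )
    for group, vname in GROUP_TO_REDUCED.items():
        fits[vname] = fit_map(
            trials, vname, sub[vname], grid=grid, prior=prior,
            warm_start=_fit_dict(fits["Full"]), **fit_kwargs,
        )
    # nesting repair: a reduced solution is feasible for Full, so if one
    # beats Full, re-polish Full starting from the best reduced solution
    best_red = max((v for n, v in fits.items() if n != "Full"), key=lambda f: f.loglik)
    if best_red.loglik > fits["Full"].loglik + 1e-6:
        refit = fit_map(
            trials, "Full", sub["Full"], grid=grid, prior=prior,
            warm_start=_fit_dict(best_red), **fit_kwargs,
        )
        if refit.loglik > fits["Full"].loglik:
            fits["Full"] = refit

    table = pd.DataFrame(
        [
            {"variant": n, "loglik": f.loglik, "n_free": f.n_free_params, "aic": f.aic}
            for n, f in fits.items()
        ]
    )
    aic_full = fits["Full"].aic
    session_effect = fits["None"].aic - aic_full > delta_aic
    group_flags = {
        group: bool(session_effect and (fits[vname].aic - aic_full > delta_aic))
        for group, vname in GROUP_TO_REDUCED.items()
    }
    return {
        "fits": fits,
        "table": table,
        "session_effect": bool(session_effect),
        "group_flags": group_flags,
        "delta_aic_criterion": delta_aic,
    }
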