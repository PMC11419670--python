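"""Session-level psychometric and chronometric analyses.

Psychometric fits model the probability of a contralateral choice as a
logistic function of signed coherence with microstimulation ('estim')
offsets on the slope and bias, in three variants:

- NoLapse:          p = f(x)
- SymmetricLapse:   p = lam + (1 - 2 lam) f(x)
- AsymmetricLapse:  p = lam_ipsi + (1 - lam_ipsi - lam_contra) f(x)

with f(x) = 1 / (1 + exp(-(Slope0 + Slope_estim E)(Coh + Bias0 + Bias_estim E)))
and lapse terms carrying their own estim offsets on stimulated trials.
Significance of estim terms is assessed by a permutation bootstrap that
shuffles stimulation labels within the session.  Chronometric fits are
per-choice ordinary least squares of RT on unsigned coherence with estim
offsets, with coefficient t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm

__all__ = [
    "PSYCH_VARIANTS",
    "PsychFit",
    "BootstrapResult",
    "ChronoFit",
    "fit_logistic",
    "select_logistic_variant",
    "bootstrap_estim_test",
    "fit_rt_linear",
]

#: Upper bound on any lapse arm; keeps predicted probabilities proper.
LAPSE_MAX = 0.45

_PARAMS = {
    "NoLapse": ["slope0", "slope_estim", "bias0", "bias_estim"],
    "SymmetricLapse": [
        "slope0", "slope_estim", "bias0", "bias_estim", "lapse0", "lapse_estim",
    ],
    "AsymmetricLapse": [
        "slope0", "slope_estim", "bias0", "bias_estim",
        "lapse_ipsi0", "lapse_ipsi_estim", "lapse_contra0", "lapse_contra_estim",
    ],
}

PSYCH_VARIANTS = tuple(_PARAMS)


@dataclass
class PsychFit:
    """Fitted psychometric function for one session."""

    variant: str
    params: dict
    loglik: float
    aic: float
    n_trials: int
    converged: bool = True
    warning: str | None = None

    def predict(self, signed_coh, estim) -> np.ndarray:
        return predict_p_contra(self.variant, self.params, signed_coh, estim)

    def estim_params(self) -> dict:
        return {k: v for k, v in self.params.items() if k.endswith("_estim")}

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": dict(self.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "warning": self.warning,
        }


def predict_p_contra(variant: str, params: dict, signed_coh, estim) -> np.ndarray:
    """Predicted probability of a contralateral choice."""
    coh = np.asarray(signed_coh, dtype=float)
    e = np.asarray(estim, dtype=float)
    slope = params["slope0"] + params["slope_estim"] * e
    bias = params["bias0"] + params["bias_estim"] * e
    f = 1.0 / (1.0 + np.exp(-slope * (coh + bias)))
    if variant == "NoLapse":
        p = f
    elif variant == "SymmetricLapse":
        lam = params["lapse0"] + params["lapse_estim"] * e
        p = lam + (1.0 - 2.0 * lam) * f
    elif variant == "AsymmetricLapse":
        lam_i = params["lapse_ipsi0"] + params["lapse_ipsi_estim"] * e
        lam_c = params["lapse_contra0"] + params["lapse_contra_estim"] * e
        p = lam_i + (1.0 - lam_i - lam_c) * f
    else:
        raise ValueError(f"unknown psychometric variant {variant!r}")
    return np.clip(p, 1e-9, 1.0 - 1e-9)


def _lapse_arms(variant: str, x: np.ndarray, names: list) -> list:
    """Effective lapse values for the control and estim arms."""
    vals = dict(zip(names, x))
    arms = []
    if variant == "SymmetricLapse":
        arms = [vals["lapse0"], vals["lapse0"] + vals["lapse_estim"]]
    elif variant == "AsymmetricLapse":
        arms = [
            vals["lapse_ipsi0"],
            vals["lapse_ipsi0"] + vals["lapse_ipsi_estim"],
            vals["lapse_contra0"],
            vals["lapse_contra0"] + vals["lapse_contra_estim"],
        ]
    return arms


def _nll_and_grad_nolapse(x, coh, e, y):
    """Analytic negative log-likelihood and gradient for the NoLapse variant."""
    s0, se, b0, be = x
    slope = s0 + se * e
    bias = b0 + be * e
    eta = slope * (coh + bias)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    r = p - y  # d(nll)/d(eta)
    g_s0 = np.sum(r * (coh + bias))
    g_se = np.sum(r * (coh + bias) * e)
    g_b0 = np.sum(r * slope)
    g_be = np.sum(r * slope * e)
    return nll, np.array([g_s0, g_se, g_b0, g_be])


def fit_logistic(
    trials: pd.DataFrame, variant: str = "NoLapse", start: dict | None = None
) -> PsychFit:
    """Bernoulli maximum-likelihood fit of one psychometric variant.

    Requires both stimulation arms and at least two coherence levels.
    Lapse parameters are box-bounded; a fit pinned at a parameter bound is
    flagged via ``warning`` (bounded-parameter contract under complete
    separation).
    """
    if variant not in _PARAMS:
        raise ValueError(f"unknown psychometric variant {variant!r}")
    if trials["signed_coh"].nunique() < 2:
        raise ValueError("need at least 2 coherence levels")
    if trials["estim"].nunique() < 2:
        raise ValueError("need both estim and control trials")
    coh = trials["signed_coh"].to_numpy(dtype=float)
    e = trials["estim"].to_numpy(dtype=bool).astype(float)
    y = (trials["choice"].to_numpy() == "contra").astype(float)

    names = _PARAMS[variant]
    bounds = []
    for n in names:
        if n == "slope0":
            bounds.append((0.01, 200.0))
        elif n == "slope_estim":
            bounds.append((-200.0, 200.0))
        elif n in ("bias0", "bias_estim"):
            bounds.append((-1.0, 1.0))
        elif n.endswith("_estim"):
            bounds.append((-LAPSE_MAX, LAPSE_MAX))
        else:
            bounds.append((0.0, LAPSE_MAX))

    def nll(x):
        arms = _lapse_arms(variant, x, names)
        pen = 0.0
        for lam in arms:
            if lam < 0.0:
                pen += 1e4 * lam * lam + 10.0
            if lam > LAPSE_MAX:
                pen += 1e4 * (lam - LAPSE_MAX) ** 2 + 10.0
        if pen > 0.0:
            return len(y) * 2.0 + pen
        params = dict(zip(names, x))
        p = predict_p_contra(variant, params, coh, e)
        return float(-np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))

    if variant == "NoLapse":
        x0 = np.array([8.0, 0.0, 0.0, 0.0])
        if start is not None:
            x0 = np.array([start.get(n, x0[i]) for i, n in enumerate(names)])
        best = optimize.minimize(
            lambda x: _nll_and_grad_nolapse(x, coh, e, y),
            x0, jac=True, method="L-BFGS-B", bounds=bounds,
        )
    else:
        starts = []
        if start is not None:
            starts.append(np.array([start.get(n, 1e-3) for n in names]))
        else:
            # multistart: nested solution (lapses ~ 0) plus a lapse-rich start
            base = fit_logistic(trials, "NoLapse")
            x0 = []
            for n in names:
                if n in base.params:
                    x0.append(base.params[n])
                elif n.endswith("_estim"):
                    x0.append(0.0)
                else:
                    x0.append(1e-3)
            starts.append(np.array(x0))
            x1 = np.array(x0)
            for i, n in enumerate(names):
                if n.endswith("0") and "lapse" in n:
                    x1[i] = 0.08
            starts.append(x1)
        best = None
        for s in starts:
            res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res

    params = dict(zip(names, best.x))
    ll = -float(best.fun)
    warning = None
    for (lo, hi), xv, n in zip(bounds, best.x, names):
        if "lapse" in n and (abs(xv - lo) < 1e-9 or abs(xv - hi) < 1e-9) and xv > 0:
            warning = "lapse parameter at bound"
    if not best.success:
        warning = (warning + "; " if warning else "") + "optimizer did not report convergence"
    return PsychFit(
        variant=variant,
        params=params,
        loglik=ll,
        aic=2.0 * len(names) - 2.0 * ll,
        n_trials=len(trials),
        converged=bool(best.success),
        warning=warning,
    )


def select_logistic_variant(trials: pd.DataFrame) -> PsychFit:
    """Fit all three variants and return the minimum-AIC fit.

    Ties (within 1e-9) are broken toward the variant with fewer
    parameters.
    """
    fits = [fit_logistic(trials, v) for v in PSYCH_VARIANTS]
    order = sorted(fits, key=lambda f: (round(f.aic, 9), len(f.params)))
    return order[0]


@dataclass
class BootstrapResult:
    """Permutation-bootstrap significance of the estim terms."""

    variant: str
    observed: dict
    null: dict  # parameter -> np.ndarray of shuffled-fit values
    p_values: dict
    n_shuffles: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "observed": dict(self.observed),
            "p_values": dict(self.p_values),
            "n_shuffles": self.n_shuffles,
            "n_failed": self.n_failed,
        }


def bootstrap_estim_test(
    trials: pd.DataFrame,
    variant: str = "NoLapse",
    n_shuffles: int = 200,
    seed: int = 0,
) -> BootstrapResult:
    """One-tailed permutation test of the psychometric estim terms.

    Stimulation labels are shuffled within the session (arm sizes
    preserved), the model is refit on each shuffled set, and the
    one-tailed p for each estim parameter is the fraction of null values
    whose magnitude is at least as large as the observed one (testing
    whether the observed value exceeds chance; conditioning the tail on
    the observed sign instead would double the false-positive rate).
    p is floored at 1 / (n_shuffles + 1).  Deterministic given ``seed``.
    """
    obs_fit = fit_logistic(trials, variant)
    observed = obs_fit.estim_params()
    rng = np.random.default_rng(seed)
    estim = trials["estim"].to_numpy(dtype=bool)
    null = {k: [] for k in observed}
    n_failed = 0
    shuffled = trials.copy()
    warm = dict(obs_fit.params)
    for k in warm:
        if k.endswith("_estim"):
            warm[k] = 0.0  # null-consistent warm start for shuffled refits
    for _ in range(n_shuffles):
        perm = rng.permutation(len(estim))
        shuffled["estim"] = estim[perm]
        try:
            f = fit_logistic(shuffled, variant, start=warm)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        for k, v in f.estim_params().items():
            null[k].append(v)
    if n_failed > 0.1 * n_shuffles:
        raise RuntimeError(
            f"{n_failed}/{n_shuffles} bootstrap refits failed; data are degenerate"
        )
    null = {k: np.asarray(v) for k, v in null.items()}
    p_values = {}
    for k, obs in observed.items():
        nd = null[k]
        n_ok = len(nd)
        count = int(np.sum(np.abs(nd) >= abs(obs)))
        p_values[k] = max(count / n_ok, 1.0 / (n_ok + 1)) if n_ok else np.nan
    return BootstrapResult(
        variant=variant,
        observed=observed,
        null=null,
        p_values=p_values,
        n_shuffles=n_shuffles,
        n_failed=n_failed,
    )


@dataclass
class ChronoFit:
    """Per-choice linear RT fit: RT = Offset0 + Offset_estim E +
    (Slope0 + Slope_estim E) * unsigned coherence."""

    choice: str
    params: dict
    p_values: dict
    t_values: dict
    n_trials: int
    rsquared: float

    def to_dict(self) -> dict:
        return {
            "choice": self.choice,
            "params": dict(self.params),
            "p_values": dict(self.p_values),
            "t_values": dict(self.t_values),
            "n_trials": self.n_trials,
            "rsquared": self.rsquared,
        }


def fit_rt_linear(trials: pd.DataFrame, choice: str) -> ChronoFit:
    """OLS chronometric fit on one choice's trials (correct and error).

    Estim terms enter only on stimulated trials; coefficient p-values are
    two-sided t-tests.  Raises on a rank-deficient design (e.g. no
    stimulated trials or a single coherence magnitude).
    """
    if choice not in ("contra", "ipsi"):
        raise ValueError("choice must be 'contra' or 'ipsi'")
    sub = trials[trials["choice"] == choice]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 trials with choice {choice!r}")
    coh_u = np.abs(sub["signed_coh"].to_numpy(dtype=float))
    if len(np.unique(coh_u)) < 2:
        raise ValueError("need >= 2 coherence magnitudes")
    e = sub["estim"].to_numpy(dtype=bool).astype(float)
    rt = sub["rt_s"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(rt), e, coh_u, e * coh_u])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError(
            "rank-deficient chronometric design (missing estim arm or "
            "coherence spread within an arm)"
        )
    model = sm.OLS(rt, X).fit()
    names = ["offset0", "offset_estim", "slope0", "slope_estim"]
    return ChronoFit(
        choice=choice,
        params=dict(zip(names, model.params)),
        p_values=dict(zip(names, model.pvalues)),
        t_values=dict(zip(names, model.tvalues)),
        n_trials=len(sub),
        rsquared=float(model.rsquared),
    )
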