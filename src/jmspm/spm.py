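"""Stochastic process model (SPM) with quadratic hazard for aging biomarkers.

The biomarker Y(t, c) follows a mean-reverting linear SDE

    dY(t, c) = a(t, c) (Y(t, c) - f1(t, c)) dt + b(t, c) dW(t),

and mortality is a U-shaped function of the biomarker,

    mu(t, c, Y) = mu0(t, c) + Q(t, c) (Y - f0(t, c))^2,

where f1 is the equilibrium (allostatic) trajectory toward which homeostatic
regulation pulls the biomarker, f0 is the age-dependent optimum ("sweet spot")
minimizing mortality, a < 0 is the negative-feedback (adaptive-capacity)
coefficient, b the volatility, Q the curvature of the mortality U-shape
(vulnerability to deviations from f0), and mu0 a Gompertz baseline hazard.
The gap |f0 - f1| is the allostatic-load measure: the mortality price of
equilibrating away from the optimum.

Parameterization: all components are linear in age (centered at t_min = 50)
with a sex shift; the baseline hazard is Gompertz in age with a log-linear
covariate term; the volatility is age-constant.  The likelihood uses the
discrete-time conditional-Gaussian recursion: between observations the
conditional mean m and variance gamma of the latent biomarker evolve as

    dm     = [a (m - f1) - 2 gamma Q (m - f0)] dt
    dgamma = [2 a gamma + b^2 - 2 Q gamma^2] dt

and survival contributes the integral of the conditional mean hazard
mu0 + Q [(m - f0)^2 + gamma].  For linear drift and quadratic log-survival
weights this Gaussian closure is exact up to time discretization.
Observations are treated as exact: the recursion restarts from (y, 0) after
each measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import _kernels

__all__ = [
    "SPMParams",
    "MomentState",
    "SPMFit",
    "LRTResult",
    "SPMData",
    "HYPOTHESES",
    "eval_components",
    "mean_hazard",
    "allostatic_load",
    "propagate_moments",
    "spm_loglik",
    "fit_spm",
    "run_hypothesis_suite",
    "gompertz_cum_hazard",
]

TMIN = 50.0

# Order must match _kernels theta layout.
_SCALAR_NAMES = [
    "aY", "bY", "betaY", "sigma1", "betaW",
    "af0", "bf0", "betaf0", "af1", "bf1", "betaf1",
    "aQ", "bQ", "betaQ", "ln_amu0", "bmu0",
]


@dataclass
class SPMParams:
    """Coefficients of the linear/Gompertz SPM parameterization.

    a(t,c)  = aY + bY (t - tmin) + betaY c        (aY < 0)
    b(t,c)  = sigma1 + betaW c                    (sigma1 > 0)
    f0(t,c) = af0 + bf0 (t - tmin) + betaf0 c
    f1(t,c) = af1 + bf1 (t - tmin) + betaf1 c
    Q(t,c)  = aQ + bQ (t - tmin) + betaQ c        (floored at 1e-12)
    ln mu0(t,c) = ln_amu0 + bmu0 (t - tmin) + betamu0 . w
    Y(t0,c) ~ N(f1(t0,c), sigma0^2)

    ``c`` is the sex code (0 female, 1 male); ``w`` is the baseline-hazard
    covariate vector whose first entry is sex.  The canonical parameterization
    restricts bY >= 0; fitting leaves bY free so that likelihood-ratio tests of
    bY = 0 retain a standard chi-square null (see package docs).
    """

    aY: float = -0.2
    bY: float = 0.0
    betaY: float = 0.0
    sigma1: float = 0.3
    betaW: float = 0.0
    af0: float = 0.0
    bf0: float = 0.0
    betaf0: float = 0.0
    af1: float = 0.0
    bf1: float = 0.0
    betaf1: float = 0.0
    aQ: float = 0.0
    bQ: float = 0.0
    betaQ: float = 0.0
    ln_amu0: float = float(np.log(1e-3))
    bmu0: float = 0.09
    betamu0: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sigma0: float = 0.5
    tmin: float = TMIN

    def __post_init__(self):
        self.betamu0 = np.atleast_1d(np.asarray(self.betamu0, dtype=float))
        if not self.aY < 0:
            raise ValueError("feedback coefficient aY must be negative")
        if not self.sigma1 > 0:
            raise ValueError("volatility sigma1 must be positive")
        if not self.sigma0 > 0:
            raise ValueError("initial SD sigma0 must be positive")

    def theta(self) -> np.ndarray:
        """Scalar parameter vector in kernel order (excludes betamu0)."""
        vals = [getattr(self, n) for n in _SCALAR_NAMES] + [self.sigma0]
        return np.array(vals, dtype=float)

    def q_negative_in(self, t_lo: float, t_hi: float, codes=(0.0, 1.0)) -> bool:
        """True if the linear Q(t,c) dips below 0 anywhere in [t_lo, t_hi]."""
        for c in codes:
            for t in (t_lo, t_hi):
                if self.aQ + self.bQ * (t - self.tmin) + self.betaQ * c < 0:
                    return True
        return False


@dataclass
class MomentState:
    """Conditional mean/variance of the latent biomarker at age t."""

    m: float
    gamma: float
    t: float

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("conditional variance must be nonnegative")


@dataclass
class SPMFit:
    params: SPMParams
    loglik: float
    converged: bool
    n_subjects: int
    n_measurements: int
    restrictions: dict = field(default_factory=dict)
    vcov: Optional[np.ndarray] = None
    free_names: Optional[list] = None
    warnings: list = field(default_factory=list)
    message: str = ""

    def se(self, name: str) -> float:
        if self.vcov is None or name not in (self.free_names or []):
            return np.nan
        i = self.free_names.index(name)
        return float(np.sqrt(max(self.vcov[i, i], 0.0)))


@dataclass
class LRTResult:
    h0_name: str
    loglik_unrestricted: float
    loglik_restricted: float
    df: int
    statistic: float
    p_value: float
    converged: bool = True


# H0 name -> (restriction map, df).  A string value ties the parameter to
# another (free) parameter.
HYPOTHESES: dict = {
    "Qzero": ({"aQ": 0.0, "bQ": 0.0, "betaQ": 0.0}, 3),
    "QnoT": ({"bQ": 0.0}, 1),
    "QnoC": ({"betaQ": 0.0}, 1),
    "AnoT": ({"bY": 0.0}, 1),
    "AnoC": ({"betaY": 0.0}, 1),
    "BnoC": ({"betaW": 0.0}, 1),
    "F1noT": ({"bf1": 0.0}, 1),
    "F1noC": ({"betaf1": 0.0}, 1),
    "F0noT": ({"bf0": 0.0}, 1),
    "F0noC": ({"betaf0": 0.0}, 1),
    "ALzero": ({"af0": "af1", "bf0": "bf1", "betaf0": "betaf1"}, 3),
    "ALnoT": ({"bf1": 0.0, "bf0": 0.0}, 2),
}


def eval_components(params: SPMParams, t, c, w=None):
    """Evaluate (a, b, f0, f1, Q, mu0) at age t and sex code c.

    ``w`` is the baseline-hazard covariate vector (first entry sex); when
    omitted it defaults to [c, 0, ...].
    """
    dt = np.asarray(t, dtype=float) - params.tmin
    a = params.aY + params.bY * dt + params.betaY * c
    b = params.sigma1 + params.betaW * c
    f0 = params.af0 + params.bf0 * dt + params.betaf0 * c
    f1 = params.af1 + params.bf1 * dt + params.betaf1 * c
    Q = params.aQ + params.bQ * dt + params.betaQ * c
    if w is None:
        w = np.zeros_like(params.betamu0)
        w[0] = c
    u = float(np.dot(params.betamu0, np.asarray(w, dtype=float)))
    mu0 = np.exp(params.ln_amu0 + params.bmu0 * dt + u)
    return a, b, f0, f1, Q, mu0


def allostatic_load(params: SPMParams, t, c) -> float:
    """|f0(t,c) - f1(t,c)|: excess-mortality price of the equilibrium level."""
    _, _, f0, f1, _, _ = eval_components(params, t, c)
    return np.abs(f0 - f1)


def mean_hazard(state: MomentState, params: SPMParams, c, w=None) -> float:
    """Conditional mean of the quadratic hazard, mu0 + Q [(m - f0)^2 + gamma]."""
    _, _, f0, _, Q, mu0 = eval_components(params, state.t, c, w=w)
    Q = max(float(Q), _kernels.Q_FLOOR)
    return float(mu0 + Q * ((state.m - f0) ** 2 + state.gamma))


def propagate_moments(
    state: MomentState, params: SPMParams, c, t_end: float,
    step: float = 0.1, w=None,
):
    """Advance the conditional moments to t_end; returns (state, cum_hazard)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t_end < state.t:
        raise ValueError("t_end precedes current state age")
    if w is None:
        w = np.zeros_like(params.betamu0)
        w[0] = c
    u = float(np.dot(params.betamu0, np.asarray(w, dtype=float)))
    th = params.theta()
    m, g, cum = _kernels.propagate(
        float(state.m), float(state.gamma), float(state.t), float(t_end),
        float(step),
        th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7],
        th[8], th[9], th[10], th[11], th[12], th[13], th[14], th[15],
        u, params.tmin, float(c),
    )
    return MomentState(m=m, gamma=g, t=float(t_end)), float(cum)


def gompertz_cum_hazard(params: SPMParams, t_start, t_end, c, w=None) -> float:
    """Closed-form integral of the Gompertz baseline over [t_start, t_end]."""
    if w is None:
        w = np.zeros_like(params.betamu0)
        w[0] = c
    u = float(np.dot(params.betamu0, np.asarray(w, dtype=float)))
    amu = np.exp(params.ln_amu0 + u)
    b = params.bmu0
    return (amu / b) * (
        np.exp(b * (t_end - params.tmin)) - np.exp(b * (t_start - params.tmin))
    )


# ---------------------------------------------------------------------------
# Likelihood over a cohort
# ---------------------------------------------------------------------------

class SPMData:
    """Flat-array view of a cohort for the SPM likelihood.

    W is the baseline-hazard covariate matrix (first column sex).
    """

    def __init__(self, t0, obs_age, obs_val, n_obs, T, delta, sex, W):
        self.t0 = np.asarray(t0, dtype=float)
        self.obs_age = np.asarray(obs_age, dtype=float)
        self.obs_val = np.asarray(obs_val, dtype=float)
        self.n_obs = np.asarray(n_obs, dtype=np.int64)
        self.T = np.asarray(T, dtype=float)
        self.delta = np.asarray(delta, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=float)
        self.W = np.asarray(W, dtype=float)
        self.n = self.t0.shape[0]
        self.n_measurements = int(self.n_obs.sum())

    @classmethod
    def from_cohort(cls, cohort, hazard_covariates: Optional[Sequence[str]] = None):
        inds = cohort.individuals
        n = len(inds)
        max_obs = max(len(ind.visit_ages) for ind in inds)
        obs_age = np.zeros((n, max_obs))
        obs_val = np.zeros((n, max_obs))
        n_obs = np.zeros(n, dtype=np.int64)
        t0 = np.zeros(n)
        T = np.zeros(n)
        delta = np.zeros(n, dtype=np.int64)
        sex = np.zeros(n)
        if hazard_covariates is None:
            hazard_covariates = sorted(inds[0].covariates.keys()) if inds[0].covariates else []
        W = np.zeros((n, 1 + len(hazard_covariates)))
        for i, ind in enumerate(inds):
            k = len(ind.visit_ages)
            n_obs[i] = k
            obs_age[i, :k] = ind.visit_ages
            obs_val[i, :k] = ind.y_values
            t0[i] = ind.t0
            T[i] = ind.event_age
            delta[i] = ind.death
            sex[i] = ind.sex
            W[i, 0] = ind.sex
            for j, name in enumerate(hazard_covariates):
                W[i, 1 + j] = ind.covariates[name]
        return cls(t0, obs_age, obs_val, n_obs, T, delta, sex, W)


def _loglik_arrays(data: SPMData, params: SPMParams, step: float) -> np.ndarray:
    u = data.W @ params.betamu0
    out = np.empty(data.n)
    _kernels.loglik_subjects(
        params.theta(), u, data.sex,
        data.t0, data.obs_age, data.obs_val, data.n_obs,
        data.T, data.delta, float(step), params.tmin, out,
    )
    return out


def spm_loglik(cohort_or_data, params: SPMParams, step: float = 0.1) -> float:
    """Total SPM log-likelihood of a cohort (sum over subjects).

    Each subject contributes the Gaussian densities of their measurements
    under the propagated conditional law, minus the accumulated conditional
    mean hazard from first visit to event/censoring age, plus the log mean
    hazard at death for deceased subjects.
    """
    data = cohort_or_data if isinstance(cohort_or_data, SPMData) else SPMData.from_cohort(cohort_or_data)
    ll = _loglik_arrays(data, params, step)
    total = float(np.sum(ll))
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _param_names(p_w: int) -> list:
    return _SCALAR_NAMES + [f"betamu0_{j}" for j in range(p_w)] + ["sigma0"]


def _pack(params: SPMParams) -> np.ndarray:
    return np.concatenate([
        [getattr(params, n) for n in _SCALAR_NAMES],
        params.betamu0,
        [params.sigma0],
    ])


def _unpack(vec: np.ndarray, p_w: int, tmin: float) -> SPMParams:
    ns = len(_SCALAR_NAMES)
    kw = {n: float(vec[i]) for i, n in enumerate(_SCALAR_NAMES)}
    return SPMParams(
        betamu0=vec[ns:ns + p_w].copy(), sigma0=float(vec[-1]), tmin=tmin, **kw,
    )


def _default_bounds(p_w: int) -> list:
    b = {
        "aY": (-20.0, -1e-6),
        "bY": (-0.5, 0.5),
        "betaY": (-5.0, 5.0),
        "sigma1": (1e-3, 20.0),
        "betaW": (-5.0, 5.0),
        "af0": (-20.0, 20.0), "bf0": (-2.0, 2.0), "betaf0": (-10.0, 10.0),
        "af1": (-20.0, 20.0), "bf1": (-2.0, 2.0), "betaf1": (-10.0, 10.0),
        "aQ": (-2.0, 2.0), "bQ": (-0.5, 0.5), "betaQ": (-2.0, 2.0),
        "ln_amu0": (-25.0, 2.0), "bmu0": (1e-4, 1.0),
    }
    out = [b[n] for n in _SCALAR_NAMES]
    out += [(-10.0, 10.0)] * p_w
    out += [(1e-3, 20.0)]
    return out


def _param_scales(p_w: int) -> list:
    s = {
        "aY": 0.1, "bY": 0.005, "betaY": 0.05,
        "sigma1": 0.05, "betaW": 0.05,
        "af0": 0.1, "bf0": 0.005, "betaf0": 0.1,
        "af1": 0.1, "bf1": 0.005, "betaf1": 0.1,
        "aQ": 0.003, "bQ": 0.0003, "betaQ": 0.003,
        "ln_amu0": 0.5, "bmu0": 0.01,
    }
    return [s[n] for n in _SCALAR_NAMES] + [0.2] * p_w + [0.05]


def default_start(data: SPMData, tmin: float = TMIN) -> SPMParams:
    """Deterministic data-driven starting values.

    Equilibrium f1 from least squares of y on (age - tmin, sex); sigma0 and
    sigma1 from the residual SD; a Gompertz-only survival prefit for the
    baseline-hazard parameters; Q seeded at 1e-3 / residual variance.
    """
    ages, vals, sexes = [], [], []
    for i in range(data.n):
        k = data.n_obs[i]
        ages.append(data.obs_age[i, :k])
        vals.append(data.obs_val[i, :k])
        sexes.append(np.full(k, data.sex[i]))
    ages = np.concatenate(ages); vals = np.concatenate(vals); sexes = np.concatenate(sexes)
    X = np.column_stack([np.ones_like(ages), ages - tmin, sexes])
    coef, *_ = np.linalg.lstsq(X, vals, rcond=None)
    resid = vals - X @ coef
    s = max(float(np.std(resid)), 1e-2)

    # Gompertz survival prefit ignoring the biomarker.
    p_w = data.W.shape[1]

    def negll(v):
        ln_a, b = v[0], v[1]
        u = data.W @ v[2:]
        dt_T = data.T - tmin
        dt_0 = data.t0 - tmin
        ll = np.sum(data.delta * (ln_a + b * dt_T + u))
        ll -= np.sum(np.exp(ln_a + u) / b * (np.exp(b * dt_T) - np.exp(b * dt_0)))
        return -ll

    v0 = np.concatenate([[np.log(0.01), 0.08], np.zeros(p_w)])
    res = optimize.minimize(
        negll, v0, method="L-BFGS-B",
        bounds=[(-25, 2), (1e-4, 1.0)] + [(-10, 10)] * p_w,
    )
    ln_a, bmu = float(res.x[0]), float(res.x[1])
    betamu = res.x[2:].copy()

    return SPMParams(
        aY=-0.1, bY=0.0, betaY=0.0,
        sigma1=s, betaW=0.0,
        af0=float(coef[0]), bf0=float(coef[1]), betaf0=float(coef[2]),
        af1=float(coef[0]), bf1=float(coef[1]), betaf1=float(coef[2]),
        aQ=1e-3 / s**2, bQ=0.0, betaQ=0.0,
        ln_amu0=ln_a, bmu0=bmu, betamu0=betamu,
        sigma0=s, tmin=tmin,
    )


def _resolve_restrictions(restrictions: Mapping, names: list):
    """Split restrictions into fixed values and ties (name -> source name)."""
    fixed, ties = {}, {}
    for k, v in (restrictions or {}).items():
        if k not in names:
            raise KeyError(f"unknown parameter {k!r}")
        if isinstance(v, str):
            if v not in names:
                raise KeyError(f"unknown tie target {v!r}")
            ties[k] = v
        else:
            fixed[k] = float(v)
    return fixed, ties


def fit_spm(
    cohort_or_data,
    step: float = 0.1,
    restrictions: Optional[Mapping] = None,
    start: Optional[SPMParams] = None,
    compute_vcov: bool = False,
    maxiter: int = 600,
) -> SPMFit:
    """Maximum-likelihood fit of the SPM under optional parameter restrictions.

    ``restrictions`` maps parameter names to fixed values, or to another
    parameter name to impose an equality tie (used by the allostatic-load
    hypotheses).  The fit is deterministic given the data and starting values.
    """
    data = cohort_or_data if isinstance(cohort_or_data, SPMData) else SPMData.from_cohort(cohort_or_data)
    if int(data.delta.sum()) < 1:
        raise ValueError("cohort contains no events; hazard parameters unidentified")
    p_w = data.W.shape[1]
    names = _param_names(p_w)
    tmin = (start or SPMParams()).tmin
    cold_start = start is None
    if cold_start:
        start = default_start(data, tmin=tmin)
    if start.betamu0.shape[0] != p_w:
        start = replace(start, betamu0=np.resize(start.betamu0, p_w))

    fixed, ties = _resolve_restrictions(restrictions, names)
    full0 = _pack(start)
    bounds_all = _default_bounds(p_w)
    free_idx = [i for i, n in enumerate(names) if n not in fixed and n not in ties]
    free_names = [names[i] for i in free_idx]
    fixed_vec = full0.copy()
    for k, v in fixed.items():
        fixed_vec[names.index(k)] = v
    tie_pairs = [(names.index(k), names.index(v)) for k, v in ties.items()]

    def expand(x):
        full = fixed_vec.copy()
        full[free_idx] = x
        for dst, src in tie_pairs:
            full[dst] = full[src]
        return full

    # Q(t,c) >= 0 is part of the model; enforce it over the observed age
    # window with a smooth quadratic penalty so the optimizer cannot exploit
    # the hinge created by hard clipping.
    t_lo, t_hi = float(data.t0.min()), float(data.T.max())
    codes = (0.0, 1.0)

    def q_violation(p):
        v = 0.0
        for cc in codes:
            for tt in (t_lo, t_hi):
                q = p.aQ + p.bQ * (tt - tmin) + p.betaQ * cc
                if q < 0:
                    v += q * q
        return v

    def negll(x):
        p = _unpack_safe(expand(x), p_w, tmin)
        if p is None:
            return 1e12
        ll = np.sum(_loglik_arrays(data, p, step))
        if not np.isfinite(ll):
            return 1e12
        return -ll + 1e6 * q_violation(p)

    # optimize in rescaled coordinates so all parameters move on a comparable
    # scale and finite-difference gradients are well conditioned
    scales_all = np.array(_param_scales(p_w))
    scales = scales_all[free_idx]
    x0 = full0[free_idx]
    bounds = [bounds_all[i] for i in free_idx]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    sbounds = [(lo / s, hi / s) for (lo, hi), s in zip(bounds, scales)]

    def negll_scaled(y):
        return negll(y * scales)

    opts = {"maxiter": maxiter, "maxfun": 60 * maxiter, "ftol": 1e-11,
            "gtol": 1e-6, "eps": 1e-6}

    def _polish(y0, rounds=None):
        """L-BFGS-B with memory-resetting restarts until the objective
        stabilizes; this likelihood has long flat valleys on small samples."""
        if rounds is None:
            rounds = 4 if cold_start else 2
        best = optimize.minimize(negll_scaled, y0, method="L-BFGS-B",
                                 bounds=sbounds, options=opts)
        for _ in range(rounds):
            nxt = optimize.minimize(negll_scaled, best.x, method="L-BFGS-B",
                                    bounds=sbounds, options=opts)
            improved = best.fun - nxt.fun
            if nxt.fun <= best.fun:
                best = nxt
            if improved < 1e-4:
                break
        return best

    res = _polish(x0 / scales)
    if cold_start:
        # staged second start: pin the age/sex terms of the hazard curvature
        # first, then release them; escapes a recurrent local optimum of the
        # full 20-parameter surface
        staged = {k: 0.0 for k in ("bQ", "betaQ")
                  if k not in fixed and k not in ties}
        if staged:
            pre = fit_spm(data, step=step,
                          restrictions={**(restrictions or {}), **staged},
                          start=start, maxiter=maxiter)
            res_b = _polish(_pack(pre.params)[free_idx] / scales)
            if res_b.fun < res.fun:
                res = res_b
    xhat = res.x * scales
    params = _unpack(expand(xhat), p_w, tmin)
    warns = []
    if params.q_negative_in(float(data.t0.min()), float(data.T.max())):
        warns.append("Q(t,c) clipped at 1e-12 inside the observed age window")
    fit = SPMFit(
        params=params, loglik=float(-res.fun), converged=bool(res.success),
        n_subjects=data.n, n_measurements=data.n_measurements,
        restrictions=dict(restrictions or {}), free_names=free_names,
        warnings=warns, message=str(res.message),
    )
    if compute_vcov:
        # Hessian in scaled coordinates (comparable curvatures), mapped back
        vcov_s = _numerical_vcov(negll_scaled, xhat / scales,
                                 steps=np.full(len(scales), 5e-3))
        fit.vcov = vcov_s * np.outer(scales, scales)
    return fit


def _unpack_safe(vec, p_w, tmin):
    try:
        return _unpack(vec, p_w, tmin)
    except ValueError:
        return None


def _numerical_vcov(negll, xhat, rel_step: float = 1e-4, steps=None) -> np.ndarray:
    """Inverse of the finite-difference Hessian of the negative log-likelihood."""
    p = len(xhat)
    h = steps if steps is not None else rel_step * np.maximum(np.abs(xhat), 1.0)
    H = np.zeros((p, p))
    f0 = negll(xhat)
    fp = np.zeros(p); fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = negll(xhat + e)
        fm[i] = negll(xhat - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = negll(xhat + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    H = 0.5 * (H + H.T)
    try:
        lam, V = np.linalg.eigh(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full((p, p), np.nan)
    # flat or negative-curvature directions leave their parameters
    # unconstrained: floor the eigenvalues so those directions report a
    # large (but bounded) variance instead of pinv's misleading zero
    floor = 1e-6 * max(lam.max(), 1e-300)
    inv = 1.0 / np.maximum(lam, floor)
    return (V * inv) @ V.T


def run_hypothesis_suite(
    cohort_or_data,
    step: float = 0.1,
    start: Optional[SPMParams] = None,
    unrestricted: Optional[SPMFit] = None,
) -> list:
    """Fit the unrestricted SPM and all 12 nested null models; LRT each.

    Restricted fits are warm-started from the unrestricted solution.  The LRT
    statistic 2 (ll_u - ll_r) is clipped at zero and referred to the
    chi-square distribution with the restriction's degrees of freedom.
    """
    data = cohort_or_data if isinstance(cohort_or_data, SPMData) else SPMData.from_cohort(cohort_or_data)
    if unrestricted is None:
        unrestricted = fit_spm(data, step=step, start=start)
    results = []
    for name, (restr, df) in HYPOTHESES.items():
        rfit = fit_spm(data, step=step, restrictions=restr, start=unrestricted.params)
        if rfit.loglik > unrestricted.loglik:
            # the restricted optimum dominates: the unrestricted fit stopped
            # early; polish it from the restricted solution
            refit = fit_spm(data, step=step, start=rfit.params)
            if refit.loglik >= unrestricted.loglik:
                unrestricted = refit
                results = [  # recompute earlier LRTs against the better fit
                    LRTResult(r.h0_name, unrestricted.loglik,
                              r.loglik_restricted, r.df,
                              max(0.0, 2.0 * (unrestricted.loglik - r.loglik_restricted)),
                              float(stats.chi2.sf(
                                  max(0.0, 2.0 * (unrestricted.loglik - r.loglik_restricted)),
                                  r.df)), r.converged)
                    for r in results
                ]
        stat = max(0.0, 2.0 * (unrestricted.loglik - rfit.loglik))
        p = float(stats.chi2.sf(stat, df))
        results.append(LRTResult(
            h0_name=name,
            loglik_unrestricted=unrestricted.loglik,
            loglik_restricted=rfit.loglik,
            df=df, statistic=stat, p_value=p,
            converged=bool(unrestricted.converged and rfit.converged),
        ))
        if rfit.loglik > unrestricted.loglik + 1e-6 * max(1.0, abs(unrestricted.loglik)):
            warnings.warn(
                f"restricted fit {name} exceeded unrestricted log-likelihood; "
                "optimizer likely stopped early on the unrestricted model"
            )
    return results
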