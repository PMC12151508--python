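"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's moment recursion and
closed-form segment integrals: the SPM oracle estimates the likelihood by
simulating latent paths and evaluating observation densities and survival
weights along them; the JM oracle integrates the random effects on a dense
Gauss-Legendre grid with numeric (trapezoid) cumulative hazards.
"""

import numpy as np
from scipy import stats

from jmspm.spm import SPMParams, eval_components


def _hazard(params: SPMParams, t, c, u, y):
    _, _, f0, _, Q, _ = eval_components(params, t, c)
    Q = np.maximum(Q, 1e-12)
    mu0 = np.exp(params.ln_amu0 + params.bmu0 * (t - params.tmin) + u)
    return mu0 + Q * (y - f0) ** 2


def _drift_vol(params: SPMParams, t, c):
    a, b, _, f1, _, _ = eval_components(params, t, c)
    return a, max(b, 1e-8), f1


def mc_transition_factor(params, c, u, t_from, y_from, t_to, y_to, h, n_paths, rng):
    """MC estimate of E[ delta(Y(t_to)-y_to) * exp(-int mu dt) | Y(t_from)=y_from ].

    Paths advance by Euler-Maruyama to t_to - h carrying the survival weight
    (left-point hazard); the final step's Gaussian transition density to y_to
    is evaluated exactly ("kernel-free" last-step conditioning).
    """
    n_steps = int(round((t_to - t_from) / h))
    assert n_steps >= 1
    y = np.full(n_paths, y_from)
    logw = np.zeros(n_paths)
    t = t_from
    for k in range(n_steps - 1):
        logw -= _hazard(params, t, c, u, y) * h
        a, b, f1 = _drift_vol(params, t, c)
        y = y + a * (y - f1) * h + b * np.sqrt(h) * rng.standard_normal(n_paths)
        t += h
    # hazard exposure of the last step, then exact one-step density
    logw -= _hazard(params, t, c, u, y) * h
    a, b, f1 = _drift_vol(params, t, c)
    mean_next = y + a * (y - f1) * h
    vals = np.exp(logw) * stats.norm.pdf(y_to, mean_next, b * np.sqrt(h))
    m = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n_paths)
    return m, se


def mc_survival_factor(params, c, u, t_from, y_from, t_end, delta, h, n_paths, rng):
    """MC estimate of E[ exp(-int mu dt) * mu(t_end)^delta | Y(t_from)=y_from ]."""
    n_steps = int(round((t_end - t_from) / h))
    y = np.full(n_paths, y_from)
    logw = np.zeros(n_paths)
    t = t_from
    for k in range(n_steps):
        logw -= _hazard(params, t, c, u, y) * h
        a, b, f1 = _drift_vol(params, t, c)
        y = y + a * (y - f1) * h + b * np.sqrt(h) * rng.standard_normal(n_paths)
        t += h
    vals = np.exp(logw)
    if delta:
        vals = vals * _hazard(params, t, c, u, y)
    m = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(n_paths)
    return m, se


def mc_subject_loglik(params, ind, h, n_paths, rng):
    """Simulation estimate of one subject's SPM log-likelihood with its SE."""
    c = float(ind.sex)
    w = np.zeros_like(params.betamu0)
    w[0] = c
    for j, name in enumerate(sorted(ind.covariates)):
        w[1 + j] = ind.covariates[name]
    u = float(params.betamu0 @ w)
    _, _, _, f1_t0, _, _ = eval_components(params, ind.t0, c)
    ll = stats.norm.logpdf(ind.y_values[0], f1_t0, params.sigma0)
    var = 0.0
    t_prev, y_prev = ind.t0, ind.y_values[0]
    for t_j, y_j in zip(ind.visit_ages[1:], ind.y_values[1:]):
        m, se = mc_transition_factor(params, c, u, t_prev, y_prev, t_j, y_j,
                                     h, n_paths, rng)
        ll += np.log(m)
        var += (se / m) ** 2
        t_prev, y_prev = t_j, y_j
    m, se = mc_survival_factor(params, c, u, t_prev, y_prev, ind.event_age,
                               ind.death, h, n_paths, rng)
    ll += np.log(m)
    var += (se / m) ** 2
    return ll, np.sqrt(var)


# ---------------------------------------------------------------------------
# JM dense-grid oracle
# ---------------------------------------------------------------------------

def jm_subject_loglik_dense(data, p, i, n_nodes=80, half_width=8.0,
                            n_time=4001):
    """Log of the random-effects integral for subject i by Gauss-Legendre
    quadrature on a wide box, with trapezoid cumulative hazards."""
    sd0 = np.sqrt(p.D[0, 0]); sd1 = np.sqrt(p.D[1, 1])
    x0, w0 = np.polynomial.legendre.leggauss(n_nodes)
    b0 = x0 * half_width * sd0
    b1 = x0 * half_width * sd1
    wt0 = w0 * half_width * sd0
    wt1 = w0 * half_width * sd1
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    WT = np.outer(wt0, wt1)

    beta_c, beta_t = p.beta[:-1], p.beta[-1]
    A = float(data.Xc[i] @ beta_c)
    k = int(data.n_obs[i])
    loglong = np.zeros_like(B0)
    for j in range(k):
        t = data.tau[i, j]
        mu = A + beta_t * t + B0 + B1 * t
        loglong += stats.norm.logpdf(data.y[i, j], mu, np.sqrt(p.sigma2))

    cov = p.D
    rv = stats.multivariate_normal(mean=[0, 0], cov=cov)
    logprior = rv.logpdf(np.dstack([B0, B1]))

    s = data.s[i]
    gw = float(data.w[i] @ p.gamma)
    tgrid = np.linspace(0.0, s, n_time)
    # step-function baseline on the grid
    seg = np.clip(np.searchsorted(data.edges, tgrid, side="right") - 1, 0,
                  data.n_seg - 1)
    h0_t = np.exp(p.log_h0)[seg]
    if p.association == "current_value":
        c0 = gw + p.alpha * (A + B0)
        c1 = p.alpha * (beta_t + B1)
    elif p.association == "int":
        c0 = gw + p.alpha0 * B0
        c1 = np.zeros_like(B1)
    elif p.association == "intslope":
        c0 = gw + p.alpha0 * B0
        c1 = p.alpha1 * B1
    else:
        c0 = np.full_like(B0, gw)
        c1 = np.zeros_like(B1)
    flat_c0 = c0.ravel(); flat_c1 = c1.ravel()
    cum = np.empty(flat_c0.shape)
    for start in range(0, flat_c0.size, 400):
        sl = slice(start, start + 400)
        haz = h0_t[None, :] * np.exp(flat_c0[sl, None] + flat_c1[sl, None] * tgrid[None, :])
        cum[sl] = np.trapezoid(haz, tgrid, axis=1)
    cum = cum.reshape(B0.shape)
    logsurv = -cum
    if data.delta[i] == 1:
        seg_i = int(np.clip(np.searchsorted(data.edges, s, side="right") - 1,
                            0, data.n_seg - 1))
        logsurv += p.log_h0[seg_i] + c0 + c1 * s

    integrand = np.exp(loglong + logprior + logsurv)
    return float(np.log(np.sum(integrand * WT)))
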