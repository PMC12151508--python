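"""Numba kernels for the stochastic-process-model likelihood and path simulation.

All kernels work on flat numpy arrays; covariate effects on the baseline
hazard enter through a per-subject linear predictor ``u_i`` computed by the
caller, so the kernels do not depend on the covariate dimension.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = 1.8378770664093453
Q_FLOOR = 1e-12
GAMMA_FLOOR = 0.0


@njit(cache=True)
def propagate(
    m, g, t_start, t_end, step,
    aY, bY, betaY, sig1, betaW,
    af0, bf0, betaf0, af1, bf1, betaf1,
    aQ, bQ, betaQ, ln_amu, bmu, u, tmin, c,
):
    """Advance conditional moments (m, g) from t_start to t_end on an Euler grid.

    Returns (m, g, cum_hazard) where cum_hazard is the integral of the
    conditional mean hazard accumulated with the left-point rule.  The grid is
    the interval divided into ceil(len/step) equal sub-steps so the endpoint is
    hit exactly.
    """
    length = t_end - t_start
    if length <= 0.0:
        return m, g, 0.0
    n_steps = int(np.ceil(length / step))
    if n_steps < 1:
        n_steps = 1
    h = length / n_steps

    b_c = sig1 + betaW * c
    if b_c < 1e-8:
        b_c = 1e-8
    b2 = b_c * b_c

    cum = 0.0
    t = t_start
    for _ in range(n_steps):
        dt = t - tmin
        a = aY + bY * dt + betaY * c
        f0 = af0 + bf0 * dt + betaf0 * c
        f1 = af1 + bf1 * dt + betaf1 * c
        Q = aQ + bQ * dt + betaQ * c
        if Q < Q_FLOOR:
            Q = Q_FLOOR
        mu0 = np.exp(ln_amu + bmu * dt + u)
        dev = m - f0
        lam = mu0 + Q * (dev * dev + g)
        cum += lam * h
        dm = (a * (m - f1) - 2.0 * g * Q * dev) * h
        dg = (2.0 * a * g + b2 - 2.0 * Q * g * g) * h
        m = m + dm
        g = g + dg
        if g < GAMMA_FLOOR:
            g = GAMMA_FLOOR
        t += h
    return m, g, cum


@njit(cache=True)
def loglik_subjects(
    theta, u, sex,
    t0, obs_age, obs_val, n_obs, T, delta,
    step, tmin, out,
):
    """Per-subject SPM log-likelihood under the conditional-Gaussian recursion.

    theta layout: [aY, bY, betaY, sig1, betaW, af0, bf0, betaf0,
                   af1, bf1, betaf1, aQ, bQ, betaQ, ln_amu, bmu, sigma0]
    ``u`` is the baseline-hazard covariate linear predictor per subject.
    """
    aY = theta[0]; bY = theta[1]; betaY = theta[2]
    sig1 = theta[3]; betaW = theta[4]
    af0 = theta[5]; bf0 = theta[6]; betaf0 = theta[7]
    af1 = theta[8]; bf1 = theta[9]; betaf1 = theta[10]
    aQ = theta[11]; bQ = theta[12]; betaQ = theta[13]
    ln_amu = theta[14]; bmu = theta[15]
    sigma0 = theta[16]

    n = t0.shape[0]
    for i in range(n):
        c = sex[i]
        ui = u[i]
        t = t0[i]
        m = af1 + bf1 * (t - tmin) + betaf1 * c
        g = sigma0 * sigma0
        cum = 0.0
        ll = 0.0
        ok = True
        for j in range(n_obs[i]):
            tj = obs_age[i, j]
            m, g, ch = propagate(
                m, g, t, tj, step,
                aY, bY, betaY, sig1, betaW,
                af0, bf0, betaf0, af1, bf1, betaf1,
                aQ, bQ, betaQ, ln_amu, bmu, ui, tmin, c,
            )
            cum += ch
            if g < 1e-300:
                ok = False
                break
            r = obs_val[i, j] - m
            ll += -0.5 * (LOG2PI + np.log(g)) - 0.5 * r * r / g
            m = obs_val[i, j]
            g = 0.0
            t = tj
        if not ok:
            out[i] = -np.inf
            continue
        m, g, ch = propagate(
            m, g, t, T[i], step,
            aY, bY, betaY, sig1, betaW,
            af0, bf0, betaf0, af1, bf1, betaf1,
            aQ, bQ, betaQ, ln_amu, bmu, ui, tmin, c,
        )
        cum += ch
        ll -= cum
        if delta[i] == 1:
            dt = T[i] - tmin
            f0 = af0 + bf0 * dt + betaf0 * c
            Q = aQ + bQ * dt + betaQ * c
            if Q < Q_FLOOR:
                Q = Q_FLOOR
            mu0 = np.exp(ln_amu + bmu * dt + ui)
            dev = m - f0
            lam = mu0 + Q * (dev * dev + g)
            ll += np.log(lam)
        out[i] = ll
    return out


@njit(cache=True)
def simulate_subjects(
    theta, u, sex,
    t0, visit2_age, horizon_age,
    z0, zmat, umat, step, tmin,
    y1, y2, death_age,
):
    """Euler-Maruyama simulation of biomarker paths with step-wise death draws.

    ``z0`` seeds the initial value Y(t0) ~ N(f1(t0,c), sigma0^2); ``zmat`` and
    ``umat`` hold pre-drawn standard normals / uniforms per step.  Death within
    a step is placed at the step's end.  ``visit2_age`` < 0 means no second
    visit is scheduled; y2 is NaN unless the subject is alive at that age.
    """
    aY = theta[0]; bY = theta[1]; betaY = theta[2]
    sig1 = theta[3]; betaW = theta[4]
    af0 = theta[5]; bf0 = theta[6]; betaf0 = theta[7]
    af1 = theta[8]; bf1 = theta[9]; betaf1 = theta[10]
    aQ = theta[11]; bQ = theta[12]; betaQ = theta[13]
    ln_amu = theta[14]; bmu = theta[15]
    sigma0 = theta[16]

    n = t0.shape[0]
    sqh = np.sqrt(step)
    for i in range(n):
        c = sex[i]
        ui = u[i]
        b_c = sig1 + betaW * c
        if b_c < 1e-8:
            b_c = 1e-8
        t = t0[i]
        y = af1 + bf1 * (t - tmin) + betaf1 * c + sigma0 * z0[i]
        y1[i] = y
        y2[i] = np.nan
        death_age[i] = -1.0
        k = 0
        got_v2 = visit2_age[i] < 0.0
        while t < horizon_age[i] - 1e-9:
            dt = t - tmin
            a = aY + bY * dt + betaY * c
            f0 = af0 + bf0 * dt + betaf0 * c
            f1 = af1 + bf1 * dt + betaf1 * c
            Q = aQ + bQ * dt + betaQ * c
            if Q < Q_FLOOR:
                Q = Q_FLOOR
            mu0 = np.exp(ln_amu + bmu * dt + ui)
            dev = y - f0
            lam = mu0 + Q * dev * dev
            p_death = 1.0 - np.exp(-lam * step)
            if umat[i, k] < p_death:
                death_age[i] = t + step
                break
            y = y + a * (y - f1) * step + b_c * sqh * zmat[i, k]
            t = t + step
            k += 1
            if (not got_v2) and t >= visit2_age[i] - 1e-9:
                y2[i] = y
                got_v2 = True
    return 0
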