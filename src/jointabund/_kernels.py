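"""Numba-compiled hot path for the posterior gradient.

Mirrors ``UnconstrainedPosterior.logp_grad`` for the non-covariate models
(the covariate-adjusted model uses the NumPy path).  The NumPy
implementation remains the reference; agreement is asserted in the test
suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=False)
def logp_grad_kernel(
    theta,
    W,
    V,
    M,
    center_mu,
    shift_e,
    obs,
    qobs,
    varying,
    sigma_beta_sq,
    sigma_Sigma_sq,
    alpha_sigma,
    kappa_sigma,
    grad,
):  # pragma: no cover - exercised via UnconstrainedPosterior
    n, q = W.shape
    off_beta = n * q
    off_sig = off_beta + q
    off_zeta = off_sig + q
    off_se = off_zeta + q

    logp = 0.0
    for k in range(theta.shape[0]):
        grad[k] = 0.0

    # decode efficiencies
    z_e = np.zeros(q)
    t_e = 1.0
    se = 1.0
    z_se = 0.0
    if varying:
        z_se = theta[off_se]
        t_e = np.exp(0.5 * z_se)
        se = np.exp(z_se)
        for j in range(q):
            if obs[j]:
                z_e[j] = theta[off_zeta + j]
            else:
                z_e[j] = t_e * theta[off_zeta + j]

    g_ze = np.zeros(q)
    g_a = np.zeros((n, q))
    a = np.empty((n, q))
    s_sig = np.empty(q)
    inv_sig = np.empty(q)
    for j in range(q):
        zs = theta[off_sig + j]
        s_sig[j] = np.exp(0.5 * zs)
        inv_sig[j] = np.exp(-zs)

    for i in range(n):
        for j in range(q):
            eta = theta[i * q + j]
            if center_mu[i, j]:
                a[i, j] = eta
            else:
                a[i, j] = theta[off_beta + j] + s_sig[j] * eta

    # Poisson on natural log mu = a - shift * z_e (observed taxa)
    for i in range(n):
        for j in range(qobs):
            zm = a[i, j]
            if shift_e[j]:
                zm -= z_e[j]
            mu = np.exp(zm)
            logp += V[i, j] * zm - mu
            r = V[i, j] - mu
            g_a[i, j] += r
            if varying and shift_e[j]:
                g_ze[j] -= r

    # multinomial on m_arg = a + (1 - shift) * z_e
    for i in range(n):
        amax = -1e308
        for j in range(q):
            m = a[i, j] if shift_e[j] else a[i, j] + z_e[j]
            a[i, j] = m  # reuse buffer as m_arg
            if m > amax:
                amax = m
        sa = 0.0
        for j in range(q):
            sa += np.exp(a[i, j] - amax)
        logsa = np.log(sa) + amax
        for j in range(q):
            m = a[i, j]
            logp += W[i, j] * m
            r = W[i, j] - M[i] * np.exp(m - logsa)
            g_a[i, j] += r
            if varying and not shift_e[j]:
                g_ze[j] += r
        logp -= M[i] * logsa

    # restore a from m_arg
    for i in range(n):
        for j in range(q):
            if not shift_e[j]:
                a[i, j] -= z_e[j]

    # prior on log mu in sampled coords: N(a; beta', Sigma)
    g_beta = np.zeros(q)
    g_sig = np.zeros(q)
    for i in range(n):
        for j in range(q):
            eta = theta[i * q + j]
            b = theta[off_beta + j]
            if center_mu[i, j]:
                r = eta - b
                logp += -0.5 * (r * r * inv_sig[j] + theta[off_sig + j])
                grad[i * q + j] = g_a[i, j] - r * inv_sig[j]
                g_beta[j] += r * inv_sig[j]
                g_sig[j] += 0.5 * (r * r * inv_sig[j] - 1.0)
            else:
                logp += -0.5 * eta * eta
                grad[i * q + j] = g_a[i, j] * s_sig[j] - eta
                g_beta[j] += g_a[i, j]
                g_sig[j] += 0.5 * g_a[i, j] * eta * s_sig[j]

    # beta prior on the natural beta = beta' - shift * z_e
    for j in range(q):
        b_nat = theta[off_beta + j]
        if shift_e[j]:
            b_nat -= z_e[j]
        logp += -0.5 * b_nat * b_nat / sigma_beta_sq
        grad[off_beta + j] = g_beta[j] - b_nat / sigma_beta_sq
        if varying and shift_e[j]:
            g_ze[j] += b_nat / sigma_beta_sq

    # lognormal prior on Sigma_jj + Jacobian
    for j in range(q):
        zs = theta[off_sig + j]
        logp += -0.5 * zs * zs / sigma_Sigma_sq
        grad[off_sig + j] = g_sig[j] - zs / sigma_Sigma_sq

    if varying:
        g_se = 0.0
        for j in range(q):
            zeta = theta[off_zeta + j]
            if obs[j]:
                logp += -0.5 * (zeta * zeta / se + z_se)
                grad[off_zeta + j] = g_ze[j] - zeta / se
                g_se += 0.5 * (zeta * zeta / se - 1.0)
            else:
                logp += -0.5 * zeta * zeta
                grad[off_zeta + j] = g_ze[j] * t_e - zeta
                g_se += 0.5 * t_e * g_ze[j] * zeta
        logp += -alpha_sigma * z_se - kappa_sigma * np.exp(-z_se)
        grad[off_se] = g_se - alpha_sigma + kappa_sigma * np.exp(-z_se)

    return logp
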