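"""Independent oracles used by the test suite.

Each helper deliberately re-derives a quantity through a different route than
the implementation under test (fixed-point solvers instead of ODE
integration, explicit loops instead of vectorized algebra, closed forms
instead of recursions), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np

from olfbayes.bulb import effective_lambda
from olfbayes.transfer import spike_slab_fgh


def picard_fixed_point(state, x, damping=0.05, tol=1e-9, max_iter=200_000):
    """Damped Picard iteration for the trial fixed point, independent of Euler.

    m <- (1-g) m + g (x - wL cbar);  cbar <- (1-g) cbar + g F(alpha(m, cbar)).
    """
    cfg = state.config
    lam = effective_lambda(state)
    s2 = np.sum(state.wF ** 2, axis=-1)
    m = np.zeros(cfg.N)
    cbar = np.full(cfg.M, cfg.c_o)
    for _ in range(max_iter):
        y = state.wF @ m
        alpha = (y + s2 * cbar - 3.0 * cfg.sigma_x ** 2) / (
            np.sqrt(lam) * cfg.sigma_x ** 2)
        F, _, _ = spike_slab_fgh(alpha, lam, cfg.c_o)
        m_new = np.maximum((1 - damping) * m + damping * (x - state.wL @ cbar),
                           -cfg.m_sp)
        c_new = np.maximum((1 - damping) * cbar + damping * F, 0.0)
        if max(np.max(np.abs(m_new - m)), np.max(np.abs(c_new - cbar))) < tol:
            return m_new, c_new
        m, cbar = m_new, c_new
    raise RuntimeError("Picard iteration did not converge")


def weight_update_closed_form(wF, rho_old, rho_new, t_new, cbar, m, sigma_x):
    """The precision-rescaled running-average form of the weight update.

    w^t = (1 - 1/t)(rho^{t-1}/rho^t) w^{t-1}
          + [<c>/(t rho^t sigma^2)] (m + w^{t-1} <c>),
    evaluated elementwise with explicit broadcasting; clipped at zero like the
    network rule.
    """
    lr = 1.0 / (t_new * rho_new * sigma_x ** 2)
    w_new = ((1.0 - 1.0 / t_new) * (rho_old / rho_new)[:, None] * wF
             + (lr * cbar)[:, None] * (m[None, :] + wF * cbar[:, None]))
    return np.maximum(w_new, 0.0)


def weight_error_bruteforce(learned_w, W_true, selectivity, rescale=1.0):
    """Loop-based re-implementation of the normalized weight error."""
    M, N = learned_w.shape
    total = 0.0
    for j in range(M):
        o = selectivity[j]
        Z = np.sum(learned_w[j]) / np.sum(W_true[:, o])
        acc = 0.0
        for i in range(N):
            acc += (learned_w[j, i] / Z - W_true[i, o]) ** 2
        total += np.sqrt(acc / N)
    return rescale * total / M


def two_pass_variance(block):
    """Textbook two-pass pooled variance over all entries."""
    flat = [float(v) for row in np.atleast_2d(block) for v in np.ravel(row)]
    mean = sum(flat) / len(flat)
    return sum((v - mean) ** 2 for v in flat) / len(flat)


def truncated_gaussian_mean(mu, lam):
    """Closed-form mean of N(mu, 1/lam) truncated to c > 0 (scipy route)."""
    from scipy.stats import truncnorm
    sd = 1.0 / np.sqrt(lam)
    return truncnorm.mean((0.0 - mu) / sd, np.inf, loc=mu, scale=sd)


def exp_tilted_truncated_mean(mu, lam, c_o):
    """Posterior mean under the exponential prior by adaptive quadrature."""
    from scipy.integrate import quad

    def unnorm(c, k):
        return c ** k * np.exp(-c / c_o - 0.5 * lam * (c - mu) ** 2)

    hi = max(mu, 0.0) + 15.0 / np.sqrt(lam)
    z = quad(unnorm, 0, hi, args=(0,), limit=200)[0]
    return quad(unnorm, 0, hi, args=(1,), limit=200)[0] / z
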