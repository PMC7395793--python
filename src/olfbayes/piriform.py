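"""Concentration-invariant piriform readout of odor presence probability.

Piriform cells estimate ``pbar_j = Pr[c_j > 0]`` from M/T input through the
sigmoidal presence transfer function H.  Four circuit variants of increasing
biological realism are implemented:

``bayes_copy``
    The non-biological reference: the readout weights are copied from the
    bulb's feedforward weights every trial and H is evaluated on the bulb's
    own posterior (requires granule-cell input, which piriform lacks).
``local``
    The readout weights are learned with the same discounted Hebbian rule as
    the bulb, with the piriform rate itself standing in for the unavailable
    granule teaching signal.
``local_lateral``
    As ``local``, plus learned lateral inhibition J among piriform cells,
    which drives competition and lets cells acquire distinct odors.
``local_lateral_feedback``
    As ``local_lateral``, plus top-down feedback: the piriform presence
    estimate replaces the fixed prior weight c_o inside the granule gain
    functions F and G, closing the cortex -> bulb loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bulb import BulbState, DynamicsInstability, effective_lambda
from .transfer import spike_slab_fgh

__all__ = [
    "PiriformState",
    "VARIANTS",
    "init_piriform",
    "piriform_lambda",
    "run_joint_dynamics",
    "update_piriform_plasticity",
    "update_lateral_inhibition",
    "granule_topdown_transfer",
    "run_circuit_trial",
]

VARIANTS = ("bayes_copy", "local", "local_lateral", "local_lateral_feedback")

#: clamp on the top-down prior weight so the spike/slab mixing stays proper
PBAR_EPS = 1e-6

#: lateral-inhibition Hebbian rate and decay target (Delta J = 0.1 p_k (-5 c_o J + p_j))
J_LEARN_RATE = 0.1
J_DECAY = 5.0
J_INIT = 0.02


@dataclass
class PiriformState:
    """Readout weights, precisions, lateral inhibition and last-trial rates.

    wP : (..., M, N) readout weights, piriform j <- M/T i
    rhoP : (..., M) readout precision factors
    J : (..., M, M) non-negative lateral inhibition, zero diagonal
    kappa_J : lateral strength multiplier applied inside the dynamics only
        (plasticity always sees the unscaled J)
    """

    wP: np.ndarray
    rhoP: np.ndarray
    J: np.ndarray
    variant: str
    kappa_J: float = 1.0
    pbar: np.ndarray = None


def init_piriform(bstate: BulbState, rng: np.random.Generator,
                  variant: str = "local_lateral_feedback",
                  kappa_J: float = 1.0) -> PiriformState:
    """Initialize the readout to match the bulb's initial statistics.

    wP is drawn from the same log-normal as the bulb weights (for
    ``bayes_copy`` it is overwritten with w^F at every trial anyway), rhoP
    starts at the bulb's initial precision, and J at 0.02 off-diagonal for
    the lateral variants.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    cfg = bstate.config
    from .bulb import SIGMA_G_INIT
    mu_g = 0.5 * (1.0 - SIGMA_G_INIT ** 2) - np.log(cfg.c_o * cfg.M)
    wP = rng.lognormal(mean=mu_g, sigma=SIGMA_G_INIT, size=bstate.wF.shape)
    rhoP = np.full(bstate.rho.shape, cfg.c_o / (cfg.sigma_x ** 2 * cfg.Z_rho))
    eye = np.eye(cfg.M)
    if variant in ("local_lateral", "local_lateral_feedback"):
        J = np.broadcast_to(J_INIT * (1.0 - eye), bstate.wF.shape[:-2] + (cfg.M, cfg.M)).copy()
    else:
        J = np.zeros(bstate.wF.shape[:-2] + (cfg.M, cfg.M))
    return PiriformState(wP=wP, rhoP=rhoP, J=J, variant=variant, kappa_J=kappa_J)


def piriform_lambda(pstate: PiriformState, bstate: BulbState) -> np.ndarray:
    """Pseudo-precision lambda^p_j of the readout, mirror of the bulb's lambda."""
    cfg = bstate.config
    s2 = np.sum(pstate.wP ** 2, axis=-1)
    return s2 / cfg.sigma_x ** 2 + cfg.N / (cfg.sigma_x ** 2 * bstate.t * pstate.rhoP)


def granule_topdown_transfer(alpha, lam, pbar):
    """Granule gain functions with the prior weight c_o replaced by pbar.

    pbar is clamped to [PBAR_EPS, 1 - PBAR_EPS] so the spike term of the
    normalizer stays finite.  Returns (F^D, G^D, H^D).
    """
    w = np.clip(pbar, PBAR_EPS, 1.0 - PBAR_EPS)
    return spike_slab_fgh(alpha, lam, w)


def _piriform_alpha(pstate, cfg, lamP, s2P, m, pbar):
    """Standardized piriform input alpha^p, including the lateral term."""
    yP = (pstate.wP @ m[..., None])[..., 0]
    lateral = pstate.kappa_J * (pstate.J @ pbar[..., None])[..., 0]
    return ((yP + s2P * pbar - cfg.sigma_x ** 2 * (3.0 + lamP * lateral))
            / (np.sqrt(lamP) * cfg.sigma_x ** 2))


def run_joint_dynamics(bstate: BulbState, pstate: PiriformState, x: np.ndarray,
                       duration: float | None = None):
    """Integrate M/T, granule and piriform rates jointly for one trial.

    Same two-step contract as the bulb alone: all weights and precisions are
    frozen; forward Euler from m = 0, cbar = c_o, pbar = c_o with floors
    m >= -m_sp, cbar >= 0, 0 <= pbar <= 1.  For ``bayes_copy`` the readout
    weights are first overwritten with w^F and the presence estimate is the
    bulb's own H; for ``local_lateral_feedback`` the granule transfer runs
    with pbar in place of c_o.  Returns (m, cbar, pbar) at steady state.
    """
    cfg = bstate.config
    if duration is None:
        duration = cfg.T_max
    if pstate.variant == "bayes_copy":
        pstate.wP = bstate.wF.copy()
        pstate.rhoP = bstate.rho.copy()

    dtype = np.dtype(cfg.dyn_dtype)
    lam = effective_lambda(bstate).astype(dtype)
    lamP = piriform_lambda(pstate, bstate).astype(dtype)
    wL = bstate.wL.astype(dtype, copy=False)
    J = pstate.J.astype(dtype, copy=False)
    x = x.astype(dtype, copy=False)
    feedback = pstate.variant == "local_lateral_feedback"
    copy_variant = pstate.variant == "bayes_copy"

    m = np.zeros(x.shape, dtype=dtype)
    cbar = np.full(lam.shape, cfg.c_o, dtype=dtype)
    pbar = np.full(lam.shape, cfg.c_o, dtype=dtype)

    n_steps = int(round(duration / cfg.dt))
    coef = dtype.type(cfg.dt / cfg.tau_r)
    sig2 = dtype.type(cfg.sigma_x ** 2)
    M = cfg.M
    # hoist per-trial constants; stack both feedforward pathways into one matmul
    inv_g = 1.0 / (np.sqrt(lam) * sig2)
    inv_gP = 1.0 / (np.sqrt(lamP) * sig2)
    w_stack = np.concatenate([bstate.wF, pstate.wP], axis=-2).astype(dtype)
    s2 = np.sum(w_stack[..., :M, :] ** 2, axis=-1)
    s2P = np.sum(w_stack[..., M:, :] ** 2, axis=-1)
    for step in range(n_steps):
        # Staggered Euler (see bulb.run_trial_dynamics): m first, then the
        # granule/piriform populations against the updated m.
        dm = x - m - (wL @ cbar[..., None])[..., 0]
        m = np.maximum(m + coef * dm, -cfg.m_sp)
        y2 = (w_stack @ m[..., None])[..., 0]
        y, yP = y2[..., :M], y2[..., M:]
        alpha = (y + s2 * cbar - 3.0 * sig2) * inv_g
        if feedback:
            F, _, _ = granule_topdown_transfer(alpha, lam, pbar)
        else:
            F, _, _ = spike_slab_fgh(alpha, lam, cfg.c_o)
        if copy_variant:
            _, _, H = spike_slab_fgh(alpha, lam, cfg.c_o)
        else:
            lateral = pstate.kappa_J * (J @ pbar[..., None])[..., 0]
            alphaP = (yP + s2P * pbar - sig2 * (3.0 + lamP * lateral)) * inv_gP
            _, _, H = spike_slab_fgh(alphaP, lamP, cfg.c_o)
        dc = F - cbar
        dp = H - pbar
        cbar = np.maximum(cbar + coef * dc, 0.0)
        pbar = np.clip(pbar + coef * dp, 0.0, 1.0)
        if not np.all(np.isfinite(cbar)) or not np.all(np.isfinite(pbar)):
            raise DynamicsInstability(
                f"non-finite rates at tau={step * cfg.dt:.1f} ms "
                f"(trial counter t={bstate.t}, dt={cfg.dt} ms)")
        if cfg.steady_tol > 0:
            resid = max(np.max(np.abs(dm)), np.max(np.abs(dc)),
                        np.max(np.abs(dp))) / cfg.tau_r
            if resid < cfg.steady_tol:
                break
    return m.astype(float), cbar.astype(float), pbar.astype(float)


def update_piriform_plasticity(pstate: PiriformState, bstate: BulbState,
                               m: np.ndarray, pbar: np.ndarray) -> PiriformState:
    """Discounted Hebbian update of the readout weights and precisions.

    Mirror of the bulb rule with the estimated first moment F (evaluated at
    the steady-state alpha^p, pre-update weights) standing in for the granule
    rate: precision integrates G, the learning rate is 1/(t rho^p sigma_x^2),
    and weights are clipped at zero.
    """
    cfg = bstate.config
    lamP = piriform_lambda(pstate, bstate)
    s2P = np.sum(pstate.wP ** 2, axis=-1)
    alphaP = _piriform_alpha(pstate, cfg, lamP, s2P, m, pbar)
    Fp, Gp, _ = spike_slab_fgh(alphaP, lamP, cfg.c_o)

    t_new = bstate.t + 1
    rho_new = (1.0 - 1.0 / t_new) * pstate.rhoP + Gp / (t_new * cfg.sigma_x ** 2)
    lr = 1.0 / (t_new * rho_new * cfg.sigma_x ** 2)
    delta = (1.0 / t_new
             + (1.0 - 1.0 / t_new) * (1.0 - pstate.rhoP / rho_new)
             - Fp ** 2 * lr)
    wP = np.maximum((1.0 - delta)[..., :, None] * pstate.wP
                    + (lr * Fp)[..., :, None] * m[..., None, :], 0.0)
    return replace(pstate, wP=wP, rhoP=rho_new, pbar=pbar)


def update_lateral_inhibition(J: np.ndarray, pbar: np.ndarray, c_o: float) -> np.ndarray:
    """Hebbian update of the lateral weights.

    Delta J_jk = 0.1 pbar_k (-5 c_o J_jk + pbar_j); J is clipped at zero and
    the diagonal forced to zero.
    """
    dJ = J_LEARN_RATE * pbar[..., None, :] * (
        -J_DECAY * c_o * J + pbar[..., :, None])
    Jn = np.maximum(J + dJ, 0.0)
    M = Jn.shape[-1]
    Jn = Jn * (1.0 - np.eye(M))
    return Jn


def run_circuit_trial(bstate: BulbState, pstate: PiriformState, x: np.ndarray,
                      learn: bool = True):
    """One full trial of the coupled bulb + piriform circuit.

    Integrates the joint dynamics, then (if ``learn``) applies, in order, the
    piriform weight/precision update, the lateral-inhibition update (lateral
    variants only), and the bulb update — the latter with the piriform
    presence estimate as prior weight in the feedback variant.  Returns the
    updated (bstate, pstate) and the steady-state rates.
    """
    from .bulb import update_plasticity

    m, cbar, pbar = run_joint_dynamics(bstate, pstate, x)
    if learn:
        if pstate.variant != "bayes_copy":
            pstate = update_piriform_plasticity(pstate, bstate, m, pbar)
            if pstate.variant in ("local_lateral", "local_lateral_feedback"):
                pstate = replace(pstate, J=update_lateral_inhibition(
                    pstate.J, pbar, bstate.config.c_o))
        else:
            pstate = replace(pstate, pbar=pbar)
        prior = None
        if pstate.variant == "local_lateral_feedback":
            prior = np.clip(pbar, PBAR_EPS, 1.0 - PBAR_EPS)
        bstate = update_plasticity(bstate, m, cbar, prior_weight=prior)
        if pstate.variant == "bayes_copy":
            pstate.wP = bstate.wF.copy()
            pstate.rhoP = bstate.rho.copy()
    return bstate, pstate, m, cbar, pbar
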