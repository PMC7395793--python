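"""Olfactory-bulb rate network with uncertainty-adaptive Hebbian plasticity.

The circuit holds the variational posterior over odors and mixing weights in
its rates and synapses: mitral/tufted (M/T) cells carry the residual
``m = x - w^L cbar``, granule cells carry the posterior mean concentration
``cbar`` through the spike-and-slab transfer function F, and the
dendro-dendritic weights ``w^F`` (M/T -> granule) and ``w^L`` (granule -> M/T)
track the posterior mean of the mixing weights.  Each weight's posterior
variance is ``1/(t * rho_j)``: a global hyperbolic decay times a per-granule
precision ``rho_j`` that integrates the estimated second moment of the cell's
concentration, so uncertain cells learn fast and confident cells learn slowly.

A trial is a two-step update: (1) integrate the rate dynamics to steady state
with the weights frozen at their previous-trial values; (2) update precision,
then weights, from the steady-state rates.

All state arrays accept an optional leading ensemble axis, so a batch of
independent circuits (e.g. for multi-seed medians) advances in lockstep
through vectorized numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .transfer import spike_slab_fgh

__all__ = [
    "SimConfig",
    "BulbState",
    "init_bulb",
    "effective_lambda",
    "run_trial_dynamics",
    "update_plasticity",
    "ablation_fixed_rate",
    "DynamicsInstability",
]

#: log-normal spread of the initial weights
SIGMA_G_INIT = 0.1

#: constant learning rates swept in the fixed-rate ablation
FIXED_RATE_ETAS = (0.01, 0.1, 1.0)

#: pinned pseudo-precisions used in the fixed-gain ablation
FIXED_GAIN_LAMBDAS = (200.0, 342.0)


class DynamicsInstability(RuntimeError):
    """Raised when the Euler integration produces non-finite rates."""


@dataclass(frozen=True)
class SimConfig:
    """Circuit and integration parameters.

    M, N : numbers of odors/granule cells and glomeruli/(M/T) cells
    c_o : prior presence probability (defaults to 3/M, i.e. three odors
        present per trial on average)
    sigma_x : glomerular noise standard deviation
    m_sp : spontaneous M/T rate (Hz); rates are floored at -m_sp
    tau_r : rate time constant (ms)
    dt : forward-Euler step (ms)
    T_max : trial duration (ms)
    t_min : initial value of the effective trial counter (suppresses the
        influence of the earliest samples on the 1/t learning-rate decay)
    Z_rho : precision initialization scale, rho_init = c_o/(sigma_x^2 Z_rho)
    steady_tol : early-exit threshold on the largest rate derivative
        (units per ms); 0 disables early exit
    gain_mode : 'adaptive' (lambda recomputed from weights and precision each
        trial) or 'fixed' (lambda pinned at ``gain_lambda``)
    rate_mode : 'adaptive' (Bayesian 1/(t rho) learning rate) or 'fixed'
        (constant learning rate ``rate_eta``)
    """

    M: int = 100
    N: int = 400
    c_o: float | None = None
    sigma_x: float = 1.0
    m_sp: float = 5.0
    tau_r: float = 50.0
    dt: float = 1.0
    T_max: float = 5000.0
    t_min: int = 100
    Z_rho: float = 0.5
    steady_tol: float = 1e-7
    gain_mode: str = "adaptive"
    gain_lambda: float | None = None
    rate_mode: str = "adaptive"
    rate_eta: float | None = None
    dyn_dtype: str = "float64"

    def __post_init__(self):
        if self.c_o is None:
            object.__setattr__(self, "c_o", 3.0 / self.M)
        if not (0.0 < self.c_o < 1.0):
            raise ValueError("c_o must be in (0, 1)")
        if self.dt >= self.tau_r:
            raise ValueError("dt must be smaller than tau_r")
        if self.T_max < self.dt:
            raise ValueError("T_max must be at least dt")
        if self.gain_mode not in ("adaptive", "fixed"):
            raise ValueError("gain_mode must be 'adaptive' or 'fixed'")
        if self.gain_mode == "fixed" and self.gain_lambda is None:
            raise ValueError("gain_mode='fixed' requires gain_lambda")
        if self.rate_mode not in ("adaptive", "fixed"):
            raise ValueError("rate_mode must be 'adaptive' or 'fixed'")
        if self.rate_mode == "fixed" and self.rate_eta is None:
            raise ValueError("rate_mode='fixed' requires rate_eta")
        if self.dyn_dtype not in ("float64", "float32"):
            raise ValueError("dyn_dtype must be 'float64' or 'float32'")


@dataclass
class BulbState:
    """All learnable circuit state plus the rates of the last integrated trial.

    wF : (..., M, N) mean feedforward weights, granule j <- M/T i
    wL : (..., N, M) mean lateral weights, M/T i <- granule j
    rho : (..., M) per-granule precision factors
    t : effective trial counter (the state holds "t-1" while a trial runs)
    m, cbar : rates at the end of the last trial
    """

    wF: np.ndarray
    wL: np.ndarray
    rho: np.ndarray
    t: int
    config: SimConfig
    m: np.ndarray = field(default=None)
    cbar: np.ndarray = field(default=None)


def init_bulb(config: SimConfig, rng: np.random.Generator, size=None) -> BulbState:
    """Initialize weights, precisions and the trial counter.

    Weights are log-normal with sigma_g = 0.1 and
    mu_g = (1 - sigma_g^2)/2 - log(c_o M), so their mean is e^{1/2}/(c_o M);
    w^L starts as the exact transpose of w^F (and, because the updates are
    symmetric, remains so).  Precisions start at c_o/(sigma_x^2 Z_rho).
    """
    mu_g = 0.5 * (1.0 - SIGMA_G_INIT ** 2) - np.log(config.c_o * config.M)
    shape = (config.M, config.N) if size is None else (size, config.M, config.N)
    wF = rng.lognormal(mean=mu_g, sigma=SIGMA_G_INIT, size=shape)
    wL = np.swapaxes(wF, -1, -2).copy()
    rho_val = config.c_o / (config.sigma_x ** 2 * config.Z_rho)
    rho = np.full(shape[:-1], rho_val)
    return BulbState(wF=wF, wL=wL, rho=rho, t=config.t_min, config=config)


def effective_lambda(state: BulbState) -> np.ndarray:
    """Per-granule pseudo-precision lambda_j of the concentration likelihood.

    Adaptive mode combines the weight diversity term sum_i (w^F_ji)^2 with the
    weight-uncertainty correction N/((t-1) rho_j); fixed-gain mode pins lambda;
    fixed-rate mode replaces the uncertainty term with N*eta.
    """
    cfg = state.config
    s2 = np.sum(state.wF ** 2, axis=-1)
    if cfg.gain_mode == "fixed":
        return np.broadcast_to(float(cfg.gain_lambda), s2.shape).copy()
    if cfg.rate_mode == "fixed":
        return (s2 + cfg.N * cfg.rate_eta) / cfg.sigma_x ** 2
    return s2 / cfg.sigma_x ** 2 + cfg.N / (cfg.sigma_x ** 2 * state.t * state.rho)


def _alpha(state, lam, s2, m, cbar):
    """Standardized granule input alpha_j given current rates."""
    cfg = state.config
    y = (state.wF @ m[..., None])[..., 0]
    return (y + s2 * cbar - 3.0 * cfg.sigma_x ** 2) / (np.sqrt(lam) * cfg.sigma_x ** 2)


def run_trial_dynamics(state: BulbState, x: np.ndarray, duration: float | None = None,
                       record_every: int | None = None):
    """Integrate the M/T-granule dynamics to steady state for one trial.

    Forward Euler from m = 0, cbar = c_o with floors m >= -m_sp, cbar >= 0.
    The weights, precision, and hence lambda are frozen for the whole trial.
    Returns (m, cbar) at tau = duration (default config.T_max), or earlier if
    the largest rate derivative drops below ``steady_tol``.  With
    ``record_every`` set, also returns the list of (tau, m, cbar) snapshots.

    Raises DynamicsInstability if rates become non-finite.
    """
    cfg = state.config
    if duration is None:
        duration = cfg.T_max
    if x.shape[-1] != cfg.N:
        raise ValueError(f"x has length {x.shape[-1]}, config has N={cfg.N}")

    dtype = np.dtype(cfg.dyn_dtype)
    lam = effective_lambda(state).astype(dtype)
    wF = state.wF.astype(dtype, copy=False)
    wL = state.wL.astype(dtype, copy=False)
    x = x.astype(dtype, copy=False)
    s2 = np.sum(wF ** 2, axis=-1)
    m = np.zeros(x.shape, dtype=dtype)
    cbar = np.full(lam.shape, cfg.c_o, dtype=dtype)

    n_steps = int(round(duration / cfg.dt))
    coef = dtype.type(cfg.dt / cfg.tau_r)
    sig2 = dtype.type(cfg.sigma_x ** 2)
    inv_g = 1.0 / (np.sqrt(lam) * sig2)
    trace = [] if record_every else None
    for step in range(n_steps):
        if trace is not None and step % record_every == 0:
            trace.append((step * cfg.dt, m.copy(), cbar.copy()))
        # Staggered Euler: m advances against the old cbar, cbar against the
        # new m.  Same fixed points as the simultaneous update, but stable for
        # the rotational modes of the excitation-inhibition loop at this dt.
        dm = x - m - (wL @ cbar[..., None])[..., 0]
        m = np.maximum(m + coef * dm, -cfg.m_sp)
        y = (wF @ m[..., None])[..., 0]
        alpha = (y + s2 * cbar - 3.0 * sig2) * inv_g
        F, _, _ = spike_slab_fgh(alpha, lam, cfg.c_o)
        dc = F - cbar
        cbar = np.maximum(cbar + coef * dc, 0.0)
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(cbar))):
            raise DynamicsInstability(
                f"non-finite rates at tau={step * cfg.dt:.1f} ms "
                f"(trial counter t={state.t}, dt={cfg.dt} ms)")
        if cfg.steady_tol > 0:
            resid = max(np.max(np.abs(dm)), np.max(np.abs(dc))) / cfg.tau_r
            if resid < cfg.steady_tol:
                break
    m = m.astype(float, copy=False)
    cbar = cbar.astype(float, copy=False)
    if trace is not None:
        trace.append((min((step + 1) * cfg.dt, duration), m.copy(), cbar.copy()))
        return m, cbar, trace
    return m, cbar


def steady_state_moments(state: BulbState, m: np.ndarray, cbar: np.ndarray,
                         prior_weight=None):
    """(F, G, H) evaluated at the trial's steady-state rates with frozen weights.

    ``prior_weight`` overrides the spike/slab mixing weight c_o (used by the
    top-down modulated circuit, which feeds the piriform presence estimate
    back into the granule gain functions).
    """
    lam = effective_lambda(state)
    s2 = np.sum(state.wF ** 2, axis=-1)
    alpha = _alpha(state, lam, s2, m, cbar)
    w = state.config.c_o if prior_weight is None else prior_weight
    return spike_slab_fgh(alpha, lam, w)


def update_plasticity(state: BulbState, m: np.ndarray, cbar: np.ndarray,
                      prior_weight=None) -> BulbState:
    """One round of dendro-dendritic plasticity from steady-state rates.

    The precision update runs first (it sets this trial's learning rate),
    using the second moment G evaluated with the pre-update weights; the
    weight update then applies the discounted Hebbian rule, with both w^F and
    w^L receiving the same symmetric increment.  Weights are clipped at zero
    and the trial counter advances.
    """
    cfg = state.config
    if cfg.rate_mode == "fixed":
        return ablation_fixed_rate(state, m, cbar, cfg.rate_eta)

    _, G, _ = steady_state_moments(state, m, cbar, prior_weight=prior_weight)
    t_new = state.t + 1
    rho_new = (1.0 - 1.0 / t_new) * state.rho + G / (t_new * cfg.sigma_x ** 2)
    if not np.all(rho_new > 0):
        raise FloatingPointError("precision became non-positive")

    lr = 1.0 / (t_new * rho_new * cfg.sigma_x ** 2)       # (..., M)
    delta = (1.0 / t_new
             + (1.0 - 1.0 / t_new) * (1.0 - state.rho / rho_new)
             - cbar ** 2 * lr)
    keep = 1.0 - delta
    hebb = lr * cbar                                      # (..., M)
    wF = np.maximum(keep[..., :, None] * state.wF
                    + hebb[..., :, None] * m[..., None, :], 0.0)
    wL = np.maximum(keep[..., None, :] * state.wL
                    + m[..., :, None] * hebb[..., None, :], 0.0)
    return replace(state, wF=wF, wL=wL, rho=rho_new, t=t_new, m=m, cbar=cbar)


def ablation_fixed_rate(state: BulbState, m: np.ndarray, cbar: np.ndarray,
                        eta: float) -> BulbState:
    """Weight update with the learning rate pinned at a constant eta.

    w gains (eta/sigma_x^2) * cbar_j * (m_i + cbar_j * w); the precision is
    left untouched (it no longer enters the learning rate) and lambda acquires
    the N*eta correction through ``effective_lambda``.
    """
    cfg = state.config
    g = eta / cfg.sigma_x ** 2
    wF = np.maximum(state.wF + g * cbar[..., :, None]
                    * (m[..., None, :] + cbar[..., :, None] * state.wF), 0.0)
    wL = np.maximum(state.wL + g * cbar[..., None, :]
                    * (m[..., :, None] + cbar[..., None, :] * state.wL), 0.0)
    return replace(state, wF=wF, wL=wL, t=state.t + 1, m=m, cbar=cbar)
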