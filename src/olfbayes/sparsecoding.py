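"""Sparse-coding baseline: MAP inference of odors plus stochastic dictionary learning.

The classic alternative to the Bayesian circuit: on each trial the
concentration estimate maximizes the (gamma-approximated) log posterior by
gradient ascent, and the weight estimate then takes one stochastic-gradient
step on the reconstruction error, followed by per-column L2 normalization to
prevent divergence.  The spike of the true prior is smoothed into a
gamma(k_c = 3, theta_c = c_o/3) density so the objective is differentiable;
this is precisely what makes the baseline data-inefficient compared to the
spike-and-slab circuit — it ignores uncertainty in both odors and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SparseCodingState",
    "init_sparse_coding",
    "sc_objective",
    "sc_infer",
    "sc_update_weights",
]

C_FLOOR = 1e-8          # keeps the log barrier finite
ETA_C_DEFAULT = 1e-5    # inference step size
ETA_W_DEFAULT = 0.5     # dictionary learning rate
K_C = 3.0               # gamma shape of the smoothed prior


@dataclass
class SparseCodingState:
    """Dictionary estimate and model hyper-parameters.

    w_hat : (..., N, M) weight estimate (columns are odor templates)
    theta_c = c_o / k_c so the smoothed prior keeps mean c_o
    """

    w_hat: np.ndarray
    c_o: float
    sigma_x: float
    eta_c: float = ETA_C_DEFAULT
    eta_w: float = ETA_W_DEFAULT

    @property
    def M(self) -> int:
        return self.w_hat.shape[-1]

    @property
    def N(self) -> int:
        return self.w_hat.shape[-2]


def _column_scale(c_o: float, M: int) -> float:
    """Target root-mean-square of each dictionary column: e/(c_o M)."""
    return np.e / (c_o * M)


def init_sparse_coding(M: int, N: int, c_o: float, sigma_x: float,
                       rng: np.random.Generator, size=None,
                       eta_c: float = ETA_C_DEFAULT,
                       eta_w: float = ETA_W_DEFAULT) -> SparseCodingState:
    """Random positive dictionary, immediately L2-normalized to the target scale."""
    shape = (N, M) if size is None else (size, N, M)
    w = rng.lognormal(mean=-np.log(c_o * M), sigma=1.0, size=shape)
    w = _normalize_columns(w, c_o, M)
    return SparseCodingState(w_hat=w, c_o=c_o, sigma_x=sigma_x,
                             eta_c=eta_c, eta_w=eta_w)


def sc_objective(x, c_hat, w_hat, sigma_x: float, c_o: float):
    """Log-posterior objective E_t (up to a constant).

    Quadratic reconstruction term plus the smoothed-prior term
    sum_j (2 log c_j - 3 c_j / c_o); requires c_hat > 0.
    """
    c_hat = np.asarray(c_hat, dtype=float)
    if np.any(c_hat <= 0.0):
        raise ValueError("sc_objective requires strictly positive c_hat")
    resid = x - (w_hat @ c_hat[..., None])[..., 0]
    data = -0.5 / sigma_x ** 2 * np.sum(resid ** 2, axis=-1)
    prior = np.sum((K_C - 1.0) * np.log(c_hat) - K_C * c_hat / c_o, axis=-1)
    return data + prior


def sc_infer(x, w_hat, c_o: float, sigma_x: float,
             eta_c: float = ETA_C_DEFAULT, max_steps: int = 100_000,
             grad_tol: float = 1e-10, c_init=None):
    """MAP inference of the concentrations by gradient ascent.

    Implements the per-step rule
        c <- c + eta_c * (w^T (x - w c) + sigma_x^2 (2/c - 3/c_o)),
    floored at a small positive value.  Iterates for ``max_steps`` (the study
    default is 100,000) or until the bracketed gradient's sup-norm falls
    below ``grad_tol``.  Raises on non-finite estimates.
    """
    x = np.asarray(x, dtype=float)
    M = w_hat.shape[-1]
    A = np.swapaxes(w_hat, -1, -2) @ w_hat          # (..., M, M)
    b = (np.swapaxes(w_hat, -1, -2) @ x[..., None])[..., 0]
    if c_init is None:
        c = np.full(b.shape, c_o)  # start at the prior mean
    else:
        c = np.array(c_init, dtype=float)
    sig2 = sigma_x ** 2
    three_over = K_C / c_o
    check_every = 200
    for step in range(max_steps):
        grad = b - (A @ c[..., None])[..., 0] + sig2 * ((K_C - 1.0) / c - three_over)
        c = np.maximum(c + eta_c * grad, C_FLOOR)
        if step % check_every == check_every - 1:
            if not np.all(np.isfinite(c)):
                raise FloatingPointError("sparse-coding inference diverged")
            if np.max(np.abs(grad)) < grad_tol:
                break
    return c


def _normalize_columns(w, c_o: float, M: int):
    """Rescale every column to root-mean-square e/(c_o M) over glomeruli."""
    N = w.shape[-2]
    rms = np.sqrt(np.sum(w ** 2, axis=-2, keepdims=True) / N)
    if np.any(rms == 0.0):
        raise FloatingPointError("zero dictionary column; cannot normalize")
    return _column_scale(c_o, M) * w / rms


def sc_update_weights(state: SparseCodingState, x, c_hat) -> SparseCodingState:
    """One stochastic-gradient dictionary step plus column renormalization."""
    resid = x - (state.w_hat @ c_hat[..., None])[..., 0]
    w = state.w_hat + state.eta_w * resid[..., :, None] * c_hat[..., None, :]
    w = _normalize_columns(w, state.c_o, state.M)
    return replace(state, w_hat=w)


def sc_trial(state: SparseCodingState, x, max_steps: int = 100_000,
             grad_tol: float = 1e-10):
    """Inference followed by a dictionary update; returns (state, c_hat)."""
    c_hat = sc_infer(x, state.w_hat, state.c_o, state.sigma_x,
                     eta_c=state.eta_c, max_steps=max_steps, grad_tol=grad_tol)
    return sc_update_weights(state, x, c_hat), c_hat
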