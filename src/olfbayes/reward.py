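"""Reward-prediction circuits and the go/no-go odor-reward association task.

A scalar error neuron receives the (delayed) reward and a learned negative
prediction: via the piriform presence code (``e_p``, association weights
``abar``) or directly from the glomeruli (``e_x``, weights ``h``).  During the
pre-reward window ``-e`` is the reward prediction; after delivery ``e`` is the
prediction error, and a Hebbian update of the association weights on that
error implements delta-rule learning.

The go/no-go protocol follows the study design: the unsupervised circuit is
pretrained and frozen, two odors are picked (one rewarded with amplitude 1.0,
one unrewarded), and on each trial one of them is presented alone at a
unit-mean gamma concentration with reward (plus Gaussian noise of variance
0.01) delivered at 2.5 s into a 5 s trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bulb import BulbState
from .environment import OdorWorld
from .piriform import PiriformState, run_joint_dynamics

__all__ = [
    "RewardState",
    "RewardTrial",
    "init_reward",
    "run_reward_trial",
    "update_reward_weights",
    "classification_performance",
    "average_error",
    "run_go_nogo",
]

REWARD_ONSET = 2500.0   # ms
READOUT_TIME = 2450.0   # ms; e is read just before reward delivery
REWARD_NOISE_VAR = 0.01  # variance of the Gaussian noise on the observed reward
ETA_A = 0.5             # piriform-route association learning rate
ETA_H = 0.0015          # glomeruli-route learning rate


@dataclass
class RewardState:
    """Association weights and learning rates; weights start at zero."""

    abar: np.ndarray
    h: np.ndarray
    eta_a: float = ETA_A
    eta_h: float = ETA_H


@dataclass(frozen=True)
class RewardTrial:
    """One go/no-go trial: which odor, at what amplitude, with what reward."""

    odor_id: np.ndarray
    concentration: np.ndarray
    R: np.ndarray


def init_reward(M: int, N: int, size=None) -> RewardState:
    shape_a = (M,) if size is None else (size, M)
    shape_h = (N,) if size is None else (size, N)
    return RewardState(abar=np.zeros(shape_a), h=np.zeros(shape_h))


def _integrate_error(e, drive, cfg, t_start, t_end):
    """First-order relaxation of the error neuron toward ``drive``.

    tau_r de/dtau = -e + drive, integrated with the circuit's Euler step;
    exact enough at dt << tau_r, and cheap because drive is constant once the
    sensory rates have settled.
    """
    n = int(round((t_end - t_start) / cfg.dt))
    decay = (1.0 - cfg.dt / cfg.tau_r) ** n
    return drive + (e - drive) * decay


def run_reward_trial(bstate: BulbState, pstate: PiriformState, rstate: RewardState,
                     x: np.ndarray, R: np.ndarray, route: str = "piriform",
                     duration: float = 5000.0):
    """Run one reward trial on the frozen circuit.

    The sensory dynamics are integrated to steady state (well before the
    2.45 s readout, since tau_r = 50 ms), the error neuron relaxes toward
    ``-prediction`` until the readout, then toward ``R - prediction`` until
    the end of the trial.  Returns (e_hat, e_post, features) where ``e_hat``
    is the pre-reward prediction readout at 2.45 s, ``e_post`` the error after
    delivery, and ``features`` the presynaptic vector for the weight update
    (pbar for the piriform route, x for the glomeruli route).
    """
    cfg = bstate.config
    if route == "piriform":
        if pstate is None:
            raise ValueError("piriform route requires a piriform state")
        _, _, pbar = run_joint_dynamics(bstate, pstate, x, duration=REWARD_ONSET)
        features = pbar
        pred = np.sum(rstate.abar * pbar, axis=-1)
    elif route == "glomeruli":
        features = x
        pred = np.sum(rstate.h * x, axis=-1)
    else:
        raise ValueError(f"route must be 'piriform' or 'glomeruli', got {route!r}")

    e = np.zeros(np.shape(pred))
    e_hat = _integrate_error(e, -pred, cfg, 0.0, READOUT_TIME)
    e = _integrate_error(e_hat, -pred, cfg, READOUT_TIME, REWARD_ONSET)
    e_post = _integrate_error(e, R - pred, cfg, REWARD_ONSET, duration)
    return e_hat, e_post, features


def update_reward_weights(rstate: RewardState, e_post, features,
                          route: str = "piriform") -> RewardState:
    """Hebbian association update on the post-reward error."""
    e = np.asarray(e_post)[..., None]
    if route == "piriform":
        return replace(rstate, abar=rstate.abar + rstate.eta_a * e * features)
    if route == "glomeruli":
        return replace(rstate, h=rstate.h + rstate.eta_h * e * features)
    raise ValueError(f"unknown route {route!r}")


def classification_performance(e_hats, rewards) -> float:
    """Fraction of trials where prediction and reward fall on the same side of 0.5.

    performance = < Theta[(R - 0.5)(-e_hat - 0.5)] >, with -e_hat the reward
    prediction read out just before delivery.
    """
    e_hats = np.asarray(e_hats, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if e_hats.size == 0:
        raise ValueError("performance undefined on an empty trial list")
    return float(np.mean((rewards - 0.5) * (-e_hats - 0.5) > 0.0))


def average_error(e_hats, rewards) -> float:
    """Root-mean-square of R + e_hat (zero for a perfect predictor)."""
    e_hats = np.asarray(e_hats, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    if e_hats.size == 0:
        raise ValueError("average error undefined on an empty trial list")
    return float(np.sqrt(np.mean((rewards + e_hats) ** 2)))


def sample_reward_trial(M: int, j_plus, j_minus, rng: np.random.Generator,
                        size=None, gamma_shape: float = 3.0) -> RewardTrial:
    """Draw one go/no-go trial: coin-flip odor, unit-mean gamma amplitude.

    The presented odor is always present (the task's "c_o = 1"); the reward is
    a_j + noise with a_{j+} = 1, a_{j-} = 0 and noise sd 0.1.
    """
    n = 1 if size is None else size
    go = rng.random(n) < 0.5
    odor = np.where(go, j_plus, j_minus)
    amp = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n)
    R = go.astype(float) + np.sqrt(REWARD_NOISE_VAR) * rng.standard_normal(n)
    if size is None:
        return RewardTrial(odor_id=odor[0], concentration=amp[0], R=R[0])
    return RewardTrial(odor_id=odor, concentration=amp, R=R)


def run_go_nogo(bstate: BulbState, pstate: PiriformState, world: OdorWorld,
                n_trials: int, rng: np.random.Generator,
                route: str = "piriform", rstate: RewardState | None = None,
                size=None):
    """Run the go/no-go task on a frozen, pretrained circuit.

    Two distinct odors are drawn at random per ensemble member.  Returns a
    dict with per-trial arrays ``e_hat`` and ``R`` of shape (n_trials,) or
    (n_trials, size), plus the final reward state; per-trial performance
    across an ensemble is then ``classification_performance(e_hat[k], R[k])``.
    """
    cfg = bstate.config
    n = 1 if size is None else size
    if rstate is None:
        rstate = init_reward(cfg.M, cfg.N, size=size)
    pair = np.array([rng.choice(cfg.M, size=2, replace=False) for _ in range(n)])
    j_plus, j_minus = pair[:, 0], pair[:, 1]

    e_hats = np.empty((n_trials, n))
    rewards = np.empty((n_trials, n))
    rows = np.arange(n)
    for k in range(n_trials):
        trial = sample_reward_trial(cfg.M, j_plus, j_minus, rng, size=n)
        c = np.zeros((n, cfg.M))
        c[rows, trial.odor_id] = trial.concentration
        clean = (world.W @ c[..., None])[..., 0]
        x = clean + world.sigma_x * rng.standard_normal(clean.shape)
        if size is None:
            x = x.reshape(cfg.N)
        e_hat, e_post, feats = run_reward_trial(
            bstate, pstate, rstate, x, trial.R, route=route)
        rstate = update_reward_weights(rstate, e_post, feats, route=route)
        e_hats[k] = e_hat
        rewards[k] = trial.R
    if size is None:
        e_hats, rewards = e_hats[:, 0], rewards[:, 0]
    return {"e_hat": e_hats, "R": rewards, "j_plus": j_plus, "j_minus": j_minus,
            "reward_state": rstate}
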