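"""Synthetic odor world: mixing weights, odor vectors and glomerular responses.

The generative model: a non-negative log-normal mixing (affinity) matrix ``W``
maps M odors onto N glomeruli; on each trial the odor concentration vector is
drawn from a sparse spike-and-slab prior (each odor independently present with
probability ``c_o``, amplitude a unit-mean gamma of shape 3); the glomerular
response is ``x = W c + sigma_x * xi`` with standard-Gaussian ``xi``.
Amplitudes represent log-concentration, so "concentration 0" means
undetectable rather than literally absent molecules.

Sampling functions accept a ``size`` argument (number of independent worlds /
trials), yielding a leading batch axis that the rest of the package carries
through the network dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdorPrior",
    "OdorWorld",
    "TrialStimulus",
    "sample_mixing_weights",
    "sample_odors",
    "glomeruli_response",
    "make_world",
    "split_rng",
]

#: hard cap on all-zero resampling attempts; exceeding it signals degenerate c_o
RESAMPLE_CAP = 10 ** 6


def split_rng(rng: np.random.Generator, n: int = 4):
    """Split a generator into independent, reproducible sub-streams.

    The conventional order used by the experiment drivers is
    (weights, odors, glomerular noise, reward noise).
    """
    return rng.spawn(n)


@dataclass(frozen=True)
class OdorPrior:
    """Spike-and-slab prior over a single odor's amplitude.

    c_o : probability that the odor is present (0 < c_o < 1)
    gamma_shape : slab shape; the rate equals the shape so the slab mean is 1
    M : number of odors in the world
    """

    c_o: float
    M: int
    gamma_shape: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.c_o < 1.0):
            raise ValueError(f"c_o must be in (0, 1), got {self.c_o}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass(frozen=True)
class OdorWorld:
    """The generative environment: mixing matrix plus noise and prior scales.

    W has shape (N, M) — or (size, N, M) for a batch of independent worlds —
    with every row sum identical within a world (enforced at sampling time).
    """

    W: np.ndarray
    sigma_x: float
    prior: OdorPrior

    @property
    def N(self) -> int:
        return self.W.shape[-2]

    @property
    def M(self) -> int:
        return self.W.shape[-1]


@dataclass(frozen=True)
class TrialStimulus:
    """One trial: concentration vector c (length M) and response x (length N)."""

    c: np.ndarray
    x: np.ndarray
    trial_index: int = 0


def sample_mixing_weights(M: int, N: int, c_o: float,
                          rng: np.random.Generator, size=None) -> np.ndarray:
    """Draw a non-negative mixing matrix with equalized row sums.

    Entries are log-normal, log w~ ~ N(-log(c_o*M), 1), then each row is
    rescaled by (grand mean of w~)/(row mean of w~).  The rescaling factor is
    1 on average but forces every row sum to equal M times the grand mean,
    removing glomerulus-to-glomerulus gain differences.
    """
    if M < 1 or N < 1:
        raise ValueError(f"M and N must be >= 1, got M={M}, N={N}")
    if not (0.0 < c_o < 1.0):
        raise ValueError(f"c_o must be in (0, 1), got {c_o}")
    shape = (N, M) if size is None else (size, N, M)
    wt = rng.lognormal(mean=-np.log(c_o * M), sigma=1.0, size=shape)
    grand = wt.mean(axis=(-2, -1), keepdims=True)
    row = wt.mean(axis=-1, keepdims=True)
    return wt * (grand / row)


def sample_odors(prior: OdorPrior, rng: np.random.Generator, size=None) -> np.ndarray:
    """Draw concentration vectors from the spike-and-slab prior.

    Each entry is 0 with probability 1 - c_o, otherwise gamma(shape, rate=shape)
    (unit mean).  All-zero vectors are resampled so every returned trial has at
    least one odor present; the resampling loop is capped at RESAMPLE_CAP
    total redraws per vector.
    """
    single = size is None
    n = 1 if single else int(size)
    c = np.zeros((n, prior.M))
    pending = np.arange(n)
    attempts = 0
    while pending.size:
        k = pending.size
        present = rng.random((k, prior.M)) < prior.c_o
        amp = rng.gamma(shape=prior.gamma_shape,
                        scale=1.0 / prior.gamma_shape,
                        size=(k, prior.M))
        c[pending] = np.where(present, amp, 0.0)
        pending = pending[~present.any(axis=1)]
        attempts += 1
        if attempts > RESAMPLE_CAP:
            raise RuntimeError(
                "all-zero odor vectors after %d resampling rounds; "
                "c_o is degenerately small" % RESAMPLE_CAP)
    return c[0] if single else c


def glomeruli_response(world: OdorWorld, c: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Noisy glomerular response x = W c + sigma_x * xi, xi ~ N(0, I)."""
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != world.M:
        raise ValueError(
            f"concentration vector has length {c.shape[-1]}, world has M={world.M}")
    clean = (world.W @ c[..., None])[..., 0]
    return clean + world.sigma_x * rng.standard_normal(clean.shape)


def make_world(M: int, N: int, c_o: float, sigma_x: float,
               rng: np.random.Generator, size=None,
               gamma_shape: float = 3.0) -> OdorWorld:
    """Convenience constructor: sample W and bundle it with prior and noise scale."""
    prior = OdorPrior(c_o=c_o, M=M, gamma_shape=gamma_shape)
    W = sample_mixing_weights(M, N, c_o, rng, size=size)
    return OdorWorld(W=W, sigma_x=sigma_x, prior=prior)
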