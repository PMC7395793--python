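"""Closed-form variational posterior machinery for the spike-and-slab odor prior.

The single-odor posterior is proportional to ``p_c(c) * exp(-lam*(c-mu)^2/2)``,
where ``p_c`` mixes a point mass at zero (odor absent, probability ``1-c_o``)
with a shape-3, unit-mean gamma slab (odor present).  For gamma shape 3 the
first moment ``F``, second moment ``G`` and presence probability ``H`` have
closed forms in the standardized argument

    alpha = sqrt(lam)*mu - 3/sqrt(lam)

and the Gaussian hazard function ``phi(alpha)/Phi(alpha)`` (the reciprocal of
the scaled Mills ratio ``Psi``).  These three functions double as the transfer
(gain) functions of the granule and piriform cells in the network model.

All functions are vectorized over numpy arrays and accept arbitrary leading
batch dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "PosteriorParams",
    "PosteriorMoments",
    "inv_psi",
    "gauss_hazard",
    "alpha_from_mu",
    "spike_slab_moments",
    "spike_slab_fgh",
    "nonneg_transfer",
    "expdecay_transfer",
    "quadrature_moments",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_BRANCH = 10.0 * np.sqrt(2.0)  # |alpha| beyond which the asymptotic branches kick in


@dataclass(frozen=True)
class PosteriorParams:
    """Gaussian pseudo-likelihood parameters of a single odor's posterior.

    mu : pseudo-mean of the Gaussian likelihood (log-concentration units)
    lam : pseudo-precision (> 0)
    c_o : prior presence probability (0 < c_o < 1)
    """

    mu: float
    lam: float
    c_o: float

    def __post_init__(self):
        if not np.all(np.asarray(self.lam) > 0):
            raise ValueError("pseudo-precision lam must be > 0")

    @property
    def alpha(self) -> float:
        return alpha_from_mu(self.mu, self.lam)


@dataclass(frozen=True)
class PosteriorMoments:
    """First moment <c>, second moment <c^2>, and Pr[c > 0]."""

    first: np.ndarray
    second: np.ndarray
    prob_present: np.ndarray


def alpha_from_mu(mu, lam):
    """Standardized argument alpha = sqrt(lam)*mu - 3/sqrt(lam) (shape-3 slab)."""
    s = np.sqrt(lam)
    return s * mu - 3.0 / s


def gauss_hazard(alpha):
    """Exact Gaussian hazard phi(alpha)/Phi(alpha) = 1/Psi(alpha).

    Computed via the scaled complementary error function, which is stable for
    arbitrarily negative alpha (where the naive ratio underflows):

        phi(a)/Phi(a) = sqrt(2/pi) / erfcx(-a/sqrt(2)).
    """
    alpha = np.asarray(alpha)
    if alpha.dtype.kind != "f":
        alpha = alpha.astype(float)
    # python-float constants stay weak scalars and preserve float32 inputs
    return 0.7978845608028654 / special.erfcx(alpha * -0.7071067811865476)


def inv_psi(alpha):
    """Three-branch network-grade approximation of 1/Psi(alpha).

    1/Psi(alpha) ~  -alpha                          for alpha/sqrt(2) < -10
                    exp(-alpha^2/2)/(sqrt(2pi)Phi)  for |alpha/sqrt(2)| <= 10
                    0                               for alpha/sqrt(2) >  10

    The middle branch equals the exact hazard; the outer branches are its
    leading asymptotes, which avoids ever forming Psi itself.
    """
    alpha = np.asarray(alpha, dtype=float)
    mid = gauss_hazard(alpha)
    out = np.where(alpha < -_BRANCH, -alpha, mid)
    out = np.where(alpha > _BRANCH, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def _fgh_from_alpha(alpha, lam, slab_weight, hazard=gauss_hazard):
    """Shared kernel: F, G, H given alpha, lam and the spike/slab mixing weight.

    ``slab_weight`` is the prior presence probability entering the spike term
    2(1-w)/(27 w) * lam^(3/2) of the normalizer Z.  Both numerator and
    denominator are multiplied through by 1/Psi so that Psi (which overflows
    for large alpha) is never formed.
    """
    alpha = np.asarray(alpha)
    if alpha.dtype.kind != "f":
        alpha = alpha.astype(float)
    lam = np.asarray(lam)
    r = hazard(alpha)  # r = 1/Psi(alpha)
    a2 = alpha * alpha
    spike = 2.0 * (1.0 - slab_weight) / (27.0 * slab_weight) * lam ** 1.5
    den = spike * r + alpha * r + 1.0 + a2
    sqlam = np.sqrt(lam)
    first = ((2.0 + a2) * r + alpha * (3.0 + a2)) / (den * sqlam)
    second = (alpha * (5.0 + a2) * r + 3.0 + 6.0 * a2 + a2 * a2) / (den * lam)
    prob = (alpha * r + 1.0 + a2) / den
    # The closed forms are exact; tiny negative values can only arise from
    # floating-point cancellation deep in the spike-dominated regime.
    first = np.clip(first, 0.0, None)
    second = np.clip(second, 0.0, None)
    prob = np.clip(prob, 0.0, 1.0)
    return first, second, prob


def spike_slab_fgh(alpha, lam, c_o, hazard=gauss_hazard):
    """Transfer functions (F, G, H) of the shape-3 spike-and-slab posterior.

    F = <c>, G = <c^2>, H = Pr[c > 0], as functions of the standardized
    input alpha.  ``c_o`` may be an array (the top-down modulated circuit
    replaces it cell-by-cell with the piriform presence estimate).
    """
    if not isinstance(c_o, np.ndarray):
        c_o = float(c_o)        # weak scalar: preserves the working dtype
    return _fgh_from_alpha(alpha, lam, c_o, hazard=hazard)


def spike_slab_moments(params: PosteriorParams) -> PosteriorMoments:
    """Posterior moments of the shape-3 spike-and-slab model at (mu, lam, c_o)."""
    alpha = alpha_from_mu(params.mu, params.lam)
    first, second, prob = spike_slab_fgh(alpha, params.lam, params.c_o)
    return PosteriorMoments(first=first, second=second, prob_present=prob)


def nonneg_transfer(mu, lam):
    """Gain functions under the improper non-negativity prior p(c) ~ Theta(c).

    F is the mean of a Gaussian(mu, 1/lam) truncated to c > 0, i.e. the
    rectified-linear-like transfer; G = mu*F + 1/lam.
    """
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not np.all(lam > 0):
        raise ValueError("lam must be > 0")
    sqlam = np.sqrt(lam)
    F = mu + gauss_hazard(sqlam * mu) / sqlam
    G = mu * F + 1.0 / lam
    return F, G


def expdecay_transfer(mu, lam, c_o):
    """Gain functions under the non-negative exponential prior p(c) = exp(-c/c_o)/c_o.

    Identical to the truncated-Gaussian transfer with the pseudo-mean shifted
    by 1/(c_o*lam); recovers ``nonneg_transfer`` as c_o -> infinity.
    """
    mu = np.asarray(mu, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if not np.all(lam > 0):
        raise ValueError("lam must be > 0")
    if not np.all(np.asarray(c_o) > 0):
        raise ValueError("c_o must be > 0")
    shifted = mu - 1.0 / (c_o * lam)
    sqlam = np.sqrt(lam)
    F = shifted + gauss_hazard(sqlam * mu - 1.0 / (c_o * sqlam)) / sqlam
    G = shifted * F + 1.0 / lam
    return F, G


# ---------------------------------------------------------------------------
# Numeric oracle
# ---------------------------------------------------------------------------

def _default_slab_shape3(c):
    """Unit-mean gamma(shape=3, rate=3) density (the paper-default slab)."""
    return 13.5 * c * c * np.exp(-3.0 * c)


def quadrature_moments(mu, lam, c_o, slab_density=None, rel_tol=1e-8,
                       max_doublings=18):
    """Posterior moments by composite Gauss-Legendre quadrature.

    Independent numeric route for the moments of
    ``(1-c_o) delta(c) + c_o slab(c)`` tilted by ``exp(-lam (c-mu)^2 / 2)``.
    The common factor ``exp(-lam mu^2 / 2)`` shared by spike and slab is
    divided out analytically, so nothing underflows even for strongly negative
    mu at large lam.  Panels are doubled until successive estimates of all
    three moments agree to ``rel_tol`` relative.

    Intended as a test oracle and as the fallback route for slab shapes other
    than 3 (for which no closed form is implemented).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if c_o == 0.0:
        z = np.float64(0.0)
        return PosteriorMoments(first=z, second=z, prob_present=z)
    if slab_density is None:
        slab_density = _default_slab_shape3

    hi = max(mu, 0.0) + 12.0 / np.sqrt(lam)

    # Rescale spike and slab by the Gaussian tilt's maximum over [0, inf)
    # (at c = max(mu, 0)) so neither side over- nor underflows.
    s = max(mu, 0.0)
    spike_weight = (1.0 - c_o) * np.exp(-0.5 * lam * (mu * mu - (s - mu) ** 2))

    def integrand(c, k):
        return c ** k * slab_density(c) * np.exp(
            -0.5 * lam * ((c - mu) ** 2 - (s - mu) ** 2))

    nodes, weights = np.polynomial.legendre.leggauss(16)
    prev = None
    n_panels = 1
    for _ in range(max_doublings + 1):
        edges = np.linspace(0.0, hi, n_panels + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * (edges[1] - edges[0])
        c = (mids[:, None] + half * nodes[None, :]).ravel()
        w = np.broadcast_to(half * weights, (n_panels, 16)).ravel()
        ints = np.array([np.sum(w * integrand(c, k)) for k in (0, 1, 2)])
        if prev is not None:
            scale = np.maximum(np.abs(ints), 1e-300)
            if np.max(np.abs(ints - prev) / scale) < rel_tol:
                prev = ints
                break
        prev = ints
        n_panels *= 2
    else:
        raise RuntimeError("quadrature did not converge; integrand too sharp")

    i0, i1, i2 = prev
    z = spike_weight + c_o * i0
    return PosteriorMoments(
        first=c_o * i1 / z,
        second=c_o * i2 / z,
        prob_present=c_o * i0 / z,
    )
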