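"""Skew-normal (SN) distribution primitives.

The SN family generalizes the normal distribution with a shape parameter
``lam`` controlling skewness: right-skewed for ``lam > 0``, left-skewed for
``lam < 0``, and exactly normal at ``lam = 0``.  Its density is

    f(s; mu, sigma, lam) = (2/sigma) * phi(z) * Phi(lam * z),   z = (s-mu)/sigma,

with ``phi``/``Phi`` the standard normal pdf/cdf.  The CDF has a closed form
in terms of Owen's T function, and the distribution admits the stochastic
representation

    S = mu + Delta * T + sqrt(Gamma) * U,

where ``T`` is a standard normal truncated below zero, ``U`` a standard
normal, and ``(Delta, Gamma)`` the *alternate* parametrization
(``Delta = sigma * delta``, ``Gamma = sigma^2 - Delta^2``,
``delta = lam / sqrt(1 + lam^2)``).  The alternate form is what makes
EM-style estimation of SN mixtures tractable: conditional on the data, the
latent ``T`` is a positive truncated normal whose first two moments have
closed forms (:func:`tn_moments`).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "SNParams",
    "AltParams",
    "TruncMoments",
    "to_alternate",
    "from_alternate",
    "sn_pdf",
    "sn_logpdf",
    "sn_cdf",
    "sn_survival",
    "sn_sample",
    "sn_mode",
    "tn_moments",
]

_LOG2 = math.log(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SNParams:
    """One SN component in canonical form: location, scale, shape."""

    mu: float
    sigma: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0.0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")
        if not (math.isfinite(self.mu) and math.isfinite(self.lam)):
            raise ValueError("mu and lam must be finite")

    @property
    def delta(self) -> float:
        """Skewness fraction ``lam / sqrt(1 + lam^2)`` in (-1, 1)."""
        return self.lam / math.hypot(1.0, self.lam)


@dataclass(frozen=True)
class AltParams:
    """Alternate parametrization (mu, Delta, Gamma) of an SN component.

    ``Delta`` is the signed scale-skew product and ``Gamma`` the residual
    variance of the stochastic representation; ``Gamma + Delta^2 = sigma^2``.
    """

    mu: float
    Delta: float
    Gamma: float

    def __post_init__(self) -> None:
        if not (self.Gamma > 0.0 and math.isfinite(self.Gamma)):
            raise ValueError(f"Gamma must be positive and finite, got {self.Gamma}")


def to_alternate(p: SNParams) -> AltParams:
    """Convert canonical (mu, sigma, lam) to alternate (mu, Delta, Gamma)."""
    delta = p.delta
    Delta = p.sigma * delta
    Gamma = p.sigma**2 - Delta**2
    return AltParams(mu=p.mu, Delta=Delta, Gamma=Gamma)


def from_alternate(a: AltParams) -> SNParams:
    """Convert alternate (mu, Delta, Gamma) back to canonical (mu, sigma, lam)."""
    sigma = math.sqrt(a.Gamma + a.Delta**2)
    lam = math.copysign(math.sqrt(a.Delta**2 / a.Gamma), a.Delta)
    return SNParams(mu=a.mu, sigma=sigma, lam=lam)


def sn_logpdf(s, p: SNParams):
    """Log density, stable arbitrarily far into either tail."""
    s = np.asarray(s, dtype=float)
    z = (s - p.mu) / p.sigma
    return (
        _LOG2
        - math.log(p.sigma)
        - 0.5 * z * z
        - _LOG_SQRT_2PI
        + special.log_ndtr(p.lam * z)
    )


def sn_pdf(s, p: SNParams):
    """Density of SN(mu, sigma, lam), vectorized over ``s``."""
    return np.exp(sn_logpdf(s, p))


def sn_cdf(s, p: SNParams):
    """CDF via Owen's T:  F(s) = Phi(z) - 2*T(z, lam)."""
    s = np.asarray(s, dtype=float)
    z = (s - p.mu) / p.sigma
    return np.clip(special.ndtr(z) - 2.0 * special.owens_t(z, p.lam), 0.0, 1.0)


def sn_survival(s, p: SNParams):
    """Survival function 1 - F(s), computed as Phi(-z) + 2*T(z, lam).

    Using ``Phi(-z)`` (rather than ``1 - Phi(z)``) keeps the right tail
    accurate, which matters when inverting FDR thresholds deep in the tail.
    """
    s = np.asarray(s, dtype=float)
    z = (s - p.mu) / p.sigma
    return np.clip(special.ndtr(-z) + 2.0 * special.owens_t(z, p.lam), 0.0, 1.0)


def sample_sn(rng: np.random.Generator, p: SNParams, size: int):
    """Draw from SN(p) via the stochastic representation S = mu + Delta*T + sqrt(Gamma)*U."""
    a = to_alternate(p)
    t = np.abs(rng.standard_normal(size))  # TN+(0,1) == |N(0,1)|
    u = rng.standard_normal(size)
    return a.mu + a.Delta * t + math.sqrt(a.Gamma) * u


def sn_sample(n: int, p: SNParams, seed: int) -> np.ndarray:
    """Deterministic sample of size ``n`` from SN(p)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sample_sn(np.random.default_rng(seed), p, n)


def _mills(a):
    """Mills-type ratio phi(a)/Phi(a), stable for very negative ``a``."""
    a = np.asarray(a, dtype=float)
    return np.exp(-0.5 * a * a - _LOG_SQRT_2PI - special.log_ndtr(a))


def _mills_scalar(a: float) -> float:
    if a > -25.0:
        return math.sqrt(2.0 / math.pi) * math.exp(-0.5 * a * a) / math.erfc(-a / math.sqrt(2.0))
    return math.exp(-0.5 * a * a - _LOG_SQRT_2PI - float(special.log_ndtr(a)))


@functools.lru_cache(maxsize=8192)
def _std_mode(lam: float) -> float:
    # Mode of SN(0, 1, lam): root of  g(z) = -z + lam * phi(lam z)/Phi(lam z).
    # Unimodality makes the root unique; for lam > 0 it lies in (0, 1).
    if lam == 0.0:
        return 0.0
    if lam < 0.0:
        return -_std_mode(-lam)

    def g(z: float) -> float:
        return -z + lam * _mills_scalar(lam * z)

    hi = 1.0
    while g(hi) > 0.0:  # defensive; g(1) < 0 for all lam > 0 in practice
        hi *= 2.0
    return optimize.brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16)


def sn_mode(p: SNParams) -> float:
    """Mode (argmax of the density); the SN density is strictly unimodal."""
    return p.mu + p.sigma * _std_mode(p.lam)


@dataclass(frozen=True)
class TruncMoments:
    """First two moments of the conditional positive truncated normal."""

    xi1: np.ndarray
    xi2: np.ndarray


def tn_moments(s, p: SNParams) -> TruncMoments:
    """Moments of T | S=s where T is the latent TN+ of the stochastic representation.

    Conditionally T ~ TN+(alpha, psi^2) with ``alpha = delta*(s-mu)/sigma`` and
    ``psi^2 = 1 - delta^2``; then with r = phi(alpha/psi)/Phi(alpha/psi),

        xi1 = alpha + psi*r,    xi2 = alpha^2 + psi^2 + alpha*psi*r.

    Stable far into the left tail (alpha/psi << 0) because the ratio r is
    evaluated through ``log_ndtr``.
    """
    s = np.asarray(s, dtype=float)
    delta = p.delta
    alpha = delta * (s - p.mu) / p.sigma
    psi = math.sqrt(1.0 - delta * delta)
    r = _mills(alpha / psi)
    xi1 = alpha + psi * r
    xi2 = alpha * alpha + psi * psi + alpha * psi * r
    return TruncMoments(xi1=xi1, xi2=xi2)
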