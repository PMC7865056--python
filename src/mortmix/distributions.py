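"""Half-normal and skew-normal building blocks.

The mortality mixture uses a unit-scale half normal for infant/child deaths
and two Azzalini skew normals for the premature/accidental and adult
components.  This module provides their densities, cumulative functions,
means and modes, together with the two coordinate systems used throughout:

* the *direct* parametrization ``(xi, omega, lam)`` — location, scale, slant —
  in which the densities are written, and
* the *centered* parametrization ``(mu, sigma, gamma)`` — mean, standard
  deviation, standardized skewness — in which the likelihood surface is
  better behaved and in which the optimizer works.

The maps between the two are closed-form and mutually inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "MAX_ABS_SKEWNESS",
    "SkewNormalDirect",
    "SkewNormalCentered",
    "half_normal_pdf",
    "half_normal_cdf",
    "skew_normal_pdf",
    "skew_normal_cdf",
    "skew_normal_mean",
    "skew_normal_sd",
    "skew_normal_mode",
    "dp_to_cp",
    "cp_to_dp",
]

#: sqrt(2/pi); the mean of the unit half normal and a recurring constant.
_B = math.sqrt(2.0 / math.pi)

#: Supremum of |skewness| attainable by the skew-normal family (the limit
#: of gamma(delta) as |delta| -> 1).  Centered parameters must stay inside.
MAX_ABS_SKEWNESS = 0.99527


@dataclass(frozen=True)
class SkewNormalDirect:
    """Skew normal in direct coordinates: location ``xi`` (years), scale
    ``omega`` (years, > 0), slant ``lam`` (dimensionless; 0 gives a normal)."""

    xi: float
    omega: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("xi", "omega", "lam"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")

    @property
    def delta(self) -> float:
        """lam / sqrt(1 + lam^2), the correlation-like slant parameter."""
        return self.lam / math.hypot(1.0, self.lam)


@dataclass(frozen=True)
class SkewNormalCentered:
    """Skew normal in centered coordinates: mean ``mu`` (years), standard
    deviation ``sigma`` (years, > 0), standardized skewness ``gamma``
    (dimensionless, |gamma| < MAX_ABS_SKEWNESS)."""

    mu: float
    sigma: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if abs(self.gamma) >= MAX_ABS_SKEWNESS:
            raise ValueError(
                f"|gamma| = {abs(self.gamma)} is not attainable by the "
                f"skew-normal family (bound {MAX_ABS_SKEWNESS})"
            )


def half_normal_pdf(x):
    """Density of the unit-scale half normal, sqrt(2/pi)*exp(-x^2/2) for
    x >= 0 and 0 below.  Models infant and child deaths; mode at age 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, _B * np.exp(-0.5 * np.square(x)), 0.0)
    return out[()] if out.ndim == 0 else out


def half_normal_cdf(x):
    """Cumulative of the unit half normal: erf(x/sqrt(2)) for x >= 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0.0, special.erf(np.maximum(x, 0.0) / math.sqrt(2.0)), 0.0)
    return out[()] if out.ndim == 0 else out


def skew_normal_pdf(x, p: SkewNormalDirect):
    """Skew-normal density (2/omega)*phi(z)*Phi(lam*z), z=(x-xi)/omega."""
    return stats.skewnorm.pdf(np.asarray(x, dtype=float), p.lam, loc=p.xi, scale=p.omega)


def skew_normal_cdf(x, p: SkewNormalDirect):
    """Skew-normal cumulative, Phi(z) - 2*T(z, lam) with Owen's T function.

    Absolute accuracy is well below 1e-10, which matters because binned
    death probabilities are differences of neighbouring cdf values.
    """
    return stats.skewnorm.cdf(np.asarray(x, dtype=float), p.lam, loc=p.xi, scale=p.omega)


def skew_normal_mean(p: SkewNormalDirect) -> float:
    """Mean xi + omega*delta*sqrt(2/pi); the component term of the
    life-expectancy decomposition."""
    return p.xi + p.omega * p.delta * _B


def skew_normal_sd(p: SkewNormalDirect) -> float:
    """Standard deviation omega*sqrt(1 - 2*delta^2/pi)."""
    return p.omega * math.sqrt(1.0 - 2.0 * p.delta**2 / math.pi)


def dp_to_cp(p: SkewNormalDirect) -> SkewNormalCentered:
    """Direct -> centered map (mean, SD, standardized skewness).

    gamma = ((4-pi)/2) * (delta*sqrt(2/pi))^3 / (1 - 2*delta^2/pi)^(3/2).
    """
    d = p.delta
    u = d * _B  # mean of the standardized skew normal
    s2 = 1.0 - u * u  # its variance
    gamma = (4.0 - math.pi) / 2.0 * u**3 / s2**1.5
    return SkewNormalCentered(mu=skew_normal_mean(p), sigma=p.omega * math.sqrt(s2), gamma=gamma)


def cp_to_dp(c: SkewNormalCentered) -> SkewNormalDirect:
    """Centered -> direct map, the closed-form inverse of :func:`dp_to_cp`.

    Solving gamma(delta) for delta: with r = (2*gamma/(4-pi))^(1/3) one has
    delta*sqrt(2/pi) = r/sqrt(1+r^2); omega and xi follow from sigma and mu.
    Rejects |gamma| at or beyond the attainable skewness bound.
    """
    r = math.copysign(abs(2.0 * c.gamma / (4.0 - math.pi)) ** (1.0 / 3.0), c.gamma)
    u = r / math.sqrt(1.0 + r * r)  # = delta * sqrt(2/pi)
    delta = u / _B
    # |gamma| < MAX_ABS_SKEWNESS (enforced by the type) keeps |delta| < 1
    lam = delta / math.sqrt(1.0 - delta * delta)
    omega = c.sigma / math.sqrt(1.0 - u * u)
    xi = c.mu - omega * u
    return SkewNormalDirect(xi=xi, omega=omega, lam=lam)


def skew_normal_mode(p: SkewNormalDirect) -> float:
    """Modal age of the skew normal, located numerically.

    The skew-normal density is unimodal, so a bounded scalar minimization of
    the negative log-density on [xi - 5*omega, xi + 5*omega] finds the unique
    maximizer; tolerance well below 1e-6 years.
    """
    if p.lam == 0.0:
        return p.xi
    res = optimize.minimize_scalar(
        lambda x: -stats.skewnorm.logpdf(x, p.lam, loc=p.xi, scale=p.omega),
        bounds=(p.xi - 5.0 * p.omega, p.xi + 5.0 * p.omega),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
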