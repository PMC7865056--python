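"""The eight-parameter mortality mixture.

The age-at-death density is

    f(x; theta) = eta * f_I(x) + (1-eta) * [alpha * f_m(x) + (1-alpha) * f_M(x)]

with f_I the unit half normal (infant/child deaths, mode fixed at age 0),
f_m a skew normal for accidental + premature deaths, and f_M a skew normal
for adult deaths.  eta and alpha are mixture weights in [0, 1].  This module
provides the density, binned death probabilities on an integer age grid,
the component areas, the three modal ages, and the closed-form decomposition
of life expectancy at birth into the three components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .distributions import (
    SkewNormalCentered,
    SkewNormalDirect,
    cp_to_dp,
    dp_to_cp,
    half_normal_cdf,
    half_normal_pdf,
    skew_normal_cdf,
    skew_normal_mean,
    skew_normal_mode,
    skew_normal_pdf,
)

__all__ = [
    "DirectParams",
    "CenteredParams",
    "AgeGrid",
    "Areas",
    "Decomposition",
    "mixture_pdf",
    "mixture_cdf",
    "bin_probabilities",
    "in_range_mass",
    "areas",
    "modes",
    "infant_component_variance",
    "decompose_e0",
]

_B = math.sqrt(2.0 / math.pi)


def _check_weight(name: str, w: float) -> None:
    if not (0.0 <= w <= 1.0) or not math.isfinite(w):
        raise ValueError(f"{name} must lie in [0, 1], got {w}")


@dataclass(frozen=True)
class DirectParams:
    """Full mixture parameter vector in direct coordinates.

    ``eta`` weights the infant half normal, ``alpha`` splits the remaining
    mass between the premature component ``m`` and the adult component ``M``.
    The labelling constraint mean(m) < mean(M) pins down which skew normal
    is "young"; the likelihood itself is invariant to swapping them.
    """

    eta: float
    alpha: float
    m: SkewNormalDirect
    M: SkewNormalDirect

    def __post_init__(self) -> None:
        _check_weight("eta", self.eta)
        _check_weight("alpha", self.alpha)
        if not skew_normal_mean(self.m) < skew_normal_mean(self.M):
            raise ValueError(
                "component labelling requires mean(m) < mean(M); "
                "swap the components (the mixture is invariant to relabelling)"
            )

    def to_centered(self) -> "CenteredParams":
        return CenteredParams(self.eta, self.alpha, dp_to_cp(self.m), dp_to_cp(self.M))


@dataclass(frozen=True)
class CenteredParams:
    """Mixture parameters with each skew normal in (mean, SD, skewness)
    coordinates — the optimizer's space."""

    eta: float
    alpha: float
    m: SkewNormalCentered
    M: SkewNormalCentered

    def __post_init__(self) -> None:
        _check_weight("eta", self.eta)
        _check_weight("alpha", self.alpha)

    def to_direct(self) -> DirectParams:
        return DirectParams(self.eta, self.alpha, cp_to_dp(self.m), cp_to_dp(self.M))


@dataclass(frozen=True)
class AgeGrid:
    """Integer single-age grid 0..omega.

    Bin ``x`` covers the half-open interval [x, x+1) for x < omega; the last
    bin is open-ended ([omega, inf)), matching the HMD "110+" convention.
    """

    omega: int = 110

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError(f"omega must be >= 1, got {self.omega}")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.omega + 1)

    @property
    def n_bins(self) -> int:
        return self.omega + 1


@dataclass(frozen=True)
class Areas:
    """Proportion of deaths in each component; sums to 1 by construction."""

    A_I: float
    A_m: float
    A_M: float


@dataclass(frozen=True)
class Decomposition:
    """Life expectancy at birth split by component: e0 = e_I + e_m + e_M.

    Each term is the component's mean age at death weighted by its mixture
    share — the mean years lived by those dying in that component.
    """

    e_I: float
    e_m: float
    e_M: float
    e0: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "e0", self.e_I + self.e_m + self.e_M)


def mixture_pdf(x, theta: DirectParams):
    """Mixture density at age(s) x: the weighted sum of the three components."""
    return (
        theta.eta * half_normal_pdf(x)
        + (1.0 - theta.eta)
        * (
            theta.alpha * skew_normal_pdf(x, theta.m)
            + (1.0 - theta.alpha) * skew_normal_pdf(x, theta.M)
        )
    )


def mixture_cdf(x, theta: DirectParams):
    """Mixture cumulative at age(s) x (skew components may carry a little
    mass below age 0, so mixture_cdf(0) can be slightly positive)."""
    return (
        theta.eta * half_normal_cdf(x)
        + (1.0 - theta.eta)
        * (
            theta.alpha * skew_normal_cdf(x, theta.m)
            + (1.0 - theta.alpha) * skew_normal_cdf(x, theta.M)
        )
    )


def bin_probabilities(theta: DirectParams, grid: AgeGrid) -> np.ndarray:
    """Death probabilities p_x = F(x+1) - F(x) on the integer grid.

    The last bin is open: p_omega = 1 - F(omega).  The vector sums to
    1 - F(0), i.e. the in-range mass; any skew-component mass below age 0
    is excluded, not renormalized (renormalizing would break the closed-form
    e0 decomposition).
    """
    edges = np.arange(grid.omega + 1, dtype=float)
    F = mixture_cdf(edges, theta)
    p = np.empty(grid.n_bins)
    p[:-1] = np.diff(F)
    p[-1] = 1.0 - F[-1]
    return np.maximum(p, 0.0)


def in_range_mass(theta: DirectParams) -> float:
    """Mixture mass at nonnegative ages, 1 - F(0)."""
    return 1.0 - float(mixture_cdf(0.0, theta))


def areas(theta: DirectParams) -> Areas:
    """Component areas A_I = eta, A_m = alpha(1-eta), A_M = (1-eta)(1-alpha)."""
    return Areas(
        A_I=theta.eta,
        A_m=theta.alpha * (1.0 - theta.eta),
        A_M=(1.0 - theta.eta) * (1.0 - theta.alpha),
    )


def modes(theta: DirectParams) -> tuple[float, float, float]:
    """The three modal ages (I, m, M).

    The infant mode is 0 by construction of the half normal; the other two
    are the numeric modes of the respective skew normals.
    """
    return 0.0, skew_normal_mode(theta.m), skew_normal_mode(theta.M)


def infant_component_variance(eta: float) -> float:
    """Variance of the weighted infant term eta*f_I: eta^2 * (1 - 2/pi).

    Depends only on the infant mixture weight, which is why eta doubles as
    a measure of how fast child mortality falls off after age 0.
    """
    _check_weight("eta", eta)
    return eta**2 * (1.0 - 2.0 / math.pi)


def decompose_e0(theta: DirectParams) -> Decomposition:
    """Closed-form life expectancy decomposition.

    e_I = eta*sqrt(2/pi); e_m = (1-eta)*alpha*mean(m);
    e_M = (1-eta)(1-alpha)*mean(M); e0 is their sum.  Uses the untruncated
    component means, exact up to the (asserted small) mass outside [0, omega].
    """
    if in_range_mass(theta) < 0.999:
        warnings.warn(
            "more than 0.1% of mixture mass lies below age 0; "
            "the closed-form e0 decomposition ignores it",
            stacklevel=2,
        )
    return Decomposition(
        e_I=theta.eta * _B,
        e_m=(1.0 - theta.eta) * theta.alpha * skew_normal_mean(theta.m),
        e_M=(1.0 - theta.eta) * (1.0 - theta.alpha) * skew_normal_mean(theta.M),
    )
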