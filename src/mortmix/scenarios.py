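"""Reference parameter scenarios for simulation and validation.

The default scenario is a low-mortality male population: 2% infant deaths,
a flat premature component centred in midlife carrying 8% of the remaining
mass, and a left-skewed adult component with its mean at 80 years.  It is
the generating truth used throughout the simulation-based checks.
"""

from __future__ import annotations

from .distributions import SkewNormalCentered
from .mixture import CenteredParams, DirectParams

__all__ = ["reference_centered", "reference_theta"]


def reference_centered() -> CenteredParams:
    """The reference truth in centered coordinates:
    eta=0.02, alpha=0.08, (mu_m, sigma_m, gamma_m) = (45, 15, 0.10),
    (mu_M, sigma_M, gamma_M) = (80, 10, -0.30)."""
    return CenteredParams(
        eta=0.02,
        alpha=0.08,
        m=SkewNormalCentered(mu=45.0, sigma=15.0, gamma=0.10),
        M=SkewNormalCentered(mu=80.0, sigma=10.0, gamma=-0.30),
    )


def reference_theta() -> DirectParams:
    """The reference truth in direct coordinates."""
    return reference_centered().to_direct()
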