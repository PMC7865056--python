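"""Maximum-likelihood fitting of the mortality mixture.

Death counts on single-age bins are multinomial with cell probabilities
given by integrating the mixture density over each age interval, so the
log-likelihood (up to the multinomial constant) is sum_x D_x * log p_x(theta).

The likelihood surface in the direct skew-normal coordinates is notoriously
ridged and multimodal, so the search runs in centered coordinates
(mean, SD, skewness per component, plus the two weights):

1. a differential-evolution global search within box bounds (population
   initialized uniformly in the box),
2. a bounded quasi-Newton (L-BFGS-B) local refinement of the DE winner,
3. a restart with a doubled population and generation budget when the
   refiner moves the log-likelihood by more than 1 unit or the solution
   sits on a bound that is not demographically meaningful.

All stochastic steps are driven by an explicit seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .distributions import MAX_ABS_SKEWNESS, SkewNormalCentered
from .mixture import AgeGrid, CenteredParams, DirectParams, bin_probabilities

__all__ = [
    "PARAM_NAMES",
    "DeathCounts",
    "ParamBounds",
    "FitResult",
    "log_likelihood",
    "fit",
    "fit_error",
    "centered_to_vector",
    "vector_to_centered",
    "neg_loglik_vectorized",
    "local_refine",
]

logger = logging.getLogger(__name__)

#: Order of the eight centered coordinates everywhere a flat vector is used.
PARAM_NAMES = ("eta", "alpha", "mu_m", "sigma_m", "gamma_m", "mu_M", "sigma_M", "gamma_M")

_B = math.sqrt(2.0 / math.pi)
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class DeathCounts:
    """Observed death counts D_x on an integer age grid."""

    grid: AgeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts length {counts.shape} does not match grid with {self.grid.n_bins} bins"
            )
        if np.any(counts < 0):
            raise ValueError("death counts must be nonnegative")
        if counts.sum() <= 0:
            raise ValueError("total death count must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def empirical_distribution(self) -> np.ndarray:
        return self.counts / self.total


@dataclass(frozen=True)
class ParamBounds:
    """Box bounds for the eight centered coordinates (order: PARAM_NAMES)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (8,) or hi.shape != (8,):
            raise ValueError("bounds must have 8 entries each")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")
        for i in (4, 7):  # the two skewness coordinates
            if lo[i] <= -MAX_ABS_SKEWNESS or hi[i] >= MAX_ABS_SKEWNESS:
                raise ValueError(
                    f"skewness bounds must lie inside (-{MAX_ABS_SKEWNESS}, {MAX_ABS_SKEWNESS})"
                )
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def default(cls) -> "ParamBounds":
        """Generous demographic ranges that exclude most label swaps:
        eta<=0.5, alpha<=0.9, young mean in [5,75], adult mean in [40,105]."""
        return cls(
            lower=np.array([0.0, 0.0, 5.0, 1.0, -0.95, 40.0, 2.0, -0.95]),
            upper=np.array([0.5, 0.9, 75.0, 40.0, 0.95, 105.0, 30.0, 0.95]),
        )

    def replace(self, **overrides: tuple[float, float]) -> "ParamBounds":
        """New bounds with per-parameter (lower, upper) overrides by name."""
        lo, hi = self.lower.copy(), self.upper.copy()
        for name, (a, b) in overrides.items():
            i = PARAM_NAMES.index(name)
            lo[i], hi[i] = a, b
        return ParamBounds(lo, hi)

    def as_pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.lower, self.upper))

    def contains(self, vec: np.ndarray, atol: float = 0.0) -> bool:
        return bool(np.all(vec >= self.lower - atol) and np.all(vec <= self.upper + atol))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood estimate with diagnostics.

    ``fit_error`` is the L1 distance between the fitted bin probabilities
    and the empirical death distribution (both normalized to ~1).
    """

    theta_cp: CenteredParams
    theta_dp: DirectParams
    loglik: float
    converged: bool
    n_restarts: int
    fitted_probabilities: np.ndarray
    fit_error: float
    seed: int | None = None


def centered_to_vector(cp: CenteredParams) -> np.ndarray:
    return np.array(
        [cp.eta, cp.alpha, cp.m.mu, cp.m.sigma, cp.m.gamma, cp.M.mu, cp.M.sigma, cp.M.gamma]
    )


def vector_to_centered(vec: np.ndarray) -> CenteredParams:
    v = np.asarray(vec, dtype=float)
    return CenteredParams(
        eta=float(v[0]),
        alpha=float(v[1]),
        m=SkewNormalCentered(mu=float(v[2]), sigma=float(v[3]), gamma=float(v[4])),
        M=SkewNormalCentered(mu=float(v[5]), sigma=float(v[6]), gamma=float(v[7])),
    )


def log_likelihood(theta: DirectParams, data: DeathCounts) -> float:
    """Multinomial log-likelihood sum_x D_x log p_x (constant term omitted).

    Probabilities are floored at 1e-300 before the log; if every bin with
    observed deaths has underflowed, theta is hopeless and a ValueError is
    raised rather than returning a meaningless number.
    """
    p = bin_probabilities(theta, data.grid)
    if np.all(p[data.counts > 0] < _LOG_FLOOR):
        raise ValueError("all observed-age probabilities underflow at this theta")
    return float(data.counts @ np.log(np.maximum(p, _LOG_FLOOR)))


# --- vectorized objective -------------------------------------------------
#
# differential_evolution(vectorized=True) sends an (8, S) array of candidate
# centered vectors; everything below is broadcast over S so one generation
# costs a handful of vectorized skew-normal cdf calls.


def _sn_cdf_vec(edges: np.ndarray, mu, sigma, gamma):
    """Skew-normal cdf at `edges` (E,) for centered parameter arrays (S,).

    Inlines the centered->direct map and Phi(z) - 2*T(z, lam) with Owen's T.
    Returns an (E, S) array.
    """
    gamma = np.asarray(gamma, dtype=float)
    r = np.cbrt(2.0 * gamma / (4.0 - math.pi))
    u = r / np.sqrt(1.0 + r * r)  # delta * sqrt(2/pi)
    delta = u / _B
    lam = delta / np.sqrt(1.0 - delta * delta)
    omega = sigma / np.sqrt(1.0 - u * u)
    xi = mu - omega * u
    z = (edges[:, None] - xi) / omega
    return special.ndtr(z) - 2.0 * special.owens_t(z, lam)


def neg_loglik_vectorized(
    X: np.ndarray, counts: np.ndarray, grid: AgeGrid, renormalize: bool = False
) -> np.ndarray:
    """Negative multinomial log-likelihood for a batch of centered vectors.

    ``X`` has shape (8,) or (8, S); returns a scalar or an (S,) array.
    No component-ordering check is applied here — the likelihood is
    label-symmetric and the guard is applied once, after optimization.

    With ``renormalize`` the bin probabilities are divided by their sum
    (the in-range mass), making the cells a proper multinomial; the
    generating parameters are then an exact stationary point on noise-free
    data, which the recovery study relies on.
    """
    X = np.asarray(X, dtype=float)
    scalar = X.ndim == 1
    if scalar:
        X = X[:, None]
    eta, alpha = X[0], X[1]
    edges = np.arange(grid.omega + 1, dtype=float)
    F_I = special.erf(edges / math.sqrt(2.0))[:, None]
    F_m = _sn_cdf_vec(edges, X[2], X[3], X[4])
    F_M = _sn_cdf_vec(edges, X[5], X[6], X[7])
    F = eta * F_I + (1.0 - eta) * (alpha * F_m + (1.0 - alpha) * F_M)
    p = np.empty((grid.n_bins, X.shape[1]))
    p[:-1] = np.diff(F, axis=0)
    p[-1] = 1.0 - F[-1]
    np.clip(p, _LOG_FLOOR, None, out=p)
    if renormalize:
        p = p / p.sum(axis=0)
    nll = -(counts @ np.log(p))
    return float(nll[0]) if scalar else nll


def _apply_label_guard(vec: np.ndarray) -> np.ndarray:
    """Swap the two skew components (and flip alpha) if the young one has
    the larger mean; the likelihood is unchanged by this relabelling."""
    if vec[2] >= vec[5]:
        vec = vec.copy()
        vec[1] = 1.0 - vec[1]
        vec[2:5], vec[5:8] = vec[5:8].copy(), vec[2:5].copy()
    return vec


def local_refine(
    x0: np.ndarray,
    counts: np.ndarray,
    grid: AgeGrid,
    bounds: ParamBounds,
    options: dict | None = None,
    renormalize: bool = False,
) -> optimize.OptimizeResult:
    """Bounded L-BFGS-B refinement of a candidate centered vector."""
    return optimize.minimize(
        neg_loglik_vectorized,
        np.asarray(x0, dtype=float),
        args=(np.asarray(counts, dtype=float), grid, renormalize),
        method="L-BFGS-B",
        bounds=bounds.as_pairs(),
        options=options or {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )


def _boundary_hit(vec: np.ndarray, bounds: ParamBounds, rtol: float = 1e-6) -> bool:
    """True when a coordinate is pinned to a bound that signals trouble.

    The weights eta and alpha resting on their *lower* bound 0 are
    demographically meaningful (absent component), so they do not count.
    """
    span = bounds.upper - bounds.lower
    at_lower = vec <= bounds.lower + rtol * span
    at_upper = vec >= bounds.upper - rtol * span
    at_lower[:2] = False
    return bool(np.any(at_lower) or np.any(at_upper))


def fit(
    data: DeathCounts,
    bounds: ParamBounds | None = None,
    *,
    seed: int | None = None,
    de_generations: int = 1000,
    popsize: int = 10,
    tol: float = 0.0,
    max_restarts: int = 2,
) -> FitResult:
    """Fit the eight-parameter mixture to death counts by multinomial ML.

    Parameters
    ----------
    data
        Observed counts per single-age bin.
    bounds
        Box bounds in centered coordinates; defaults to generous
        demographic ranges.
    seed
        Seed for the DE population and mutation stream.  When None, a seed
        is drawn from entropy and logged so the run can be reproduced.
    de_generations, popsize
        DE budget: number of generations and the population multiplier
        (population size is ``popsize * 8``).
    tol
        DE's relative convergence tolerance.  The default 0 disables early
        stopping (the log-likelihood magnitude grows with N, which makes
        relative population-spread criteria fire far from the optimum) and
        runs the full generation budget.
    max_restarts
        How many times to rerun DE with doubled population and generations
        when the refinement diagnostics look bad.
    """
    bounds = bounds or ParamBounds.default()
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        logger.info("fit: no seed given, using entropy seed %d", seed)
    rng = np.random.default_rng(seed)
    counts = np.asarray(data.counts, dtype=float)

    best_vec, best_nll = None, np.inf
    n_restarts = 0
    converged = False
    gens, pop = de_generations, popsize
    for attempt in range(max_restarts + 1):
        de = optimize.differential_evolution(
            neg_loglik_vectorized,
            bounds.as_pairs(),
            args=(counts, data.grid),
            maxiter=gens,
            popsize=pop,
            init="random",
            mutation=(0.5, 1.0),
            recombination=0.9,
            tol=tol,
            seed=rng,
            polish=False,
            vectorized=True,
            updating="deferred",
        )
        logger.debug("DE attempt %d: nll=%.6f after %d iterations", attempt, de.fun, de.nit)
        local = local_refine(de.x, counts, data.grid, bounds)
        vec, nll = (local.x, local.fun) if local.fun <= de.fun else (de.x, de.fun)
        if nll < best_nll:
            best_vec, best_nll = vec, nll
        moved = de.fun - local.fun
        if moved <= 1.0 and not _boundary_hit(vec, bounds):
            converged = True
            break
        if attempt < max_restarts:
            n_restarts += 1
            gens, pop = gens * 2, pop * 2
            logger.info(
                "fit: restart %d (refiner moved loglik by %.3f or bound hit); "
                "doubling to %d generations, popsize %d",
                n_restarts,
                moved,
                gens,
                pop,
            )
    if not converged:
        warnings.warn(
            f"fit did not satisfy convergence diagnostics after {n_restarts} restarts; "
            "estimates returned with converged=False",
            stacklevel=2,
        )

    best_vec = _apply_label_guard(np.asarray(best_vec))
    theta_cp = vector_to_centered(best_vec)
    theta_dp = theta_cp.to_direct()
    p_hat = bin_probabilities(theta_dp, data.grid)
    return FitResult(
        theta_cp=theta_cp,
        theta_dp=theta_dp,
        loglik=-float(best_nll),
        converged=converged,
        n_restarts=n_restarts,
        fitted_probabilities=p_hat,
        fit_error=float(np.abs(p_hat - data.empirical_distribution).sum()),
        seed=seed,
    )


def fit_error(result: FitResult, data: DeathCounts) -> float:
    """L1 distance between fitted and empirical death distributions,
    sum_x |p_hat_x - D_x/N|; bounded by 2, near 0 for a good fit."""
    return float(np.abs(result.fitted_probabilities - data.empirical_distribution).sum())
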