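import numpy as np
import pytest

import mortmix as mm


@pytest.fixture(scope="session")
def ref_theta() -> mm.DirectParams:
    """The low-mortality reference truth used across simulation tests."""
    return mm.reference_theta()


@pytest.fixture(scope="session")
def grid() -> mm.AgeGrid:
    return mm.AgeGrid()


@pytest.fixture(scope="session")
def big_counts(ref_theta, grid) -> mm.DeathCounts:
    """One million simulated deaths from the reference truth, fixed seed."""
    return mm.simulate_death_counts(ref_theta, 10**6, grid, seed=42)


@pytest.fixture(scope="session")
def big_fit(big_counts) -> mm.FitResult:
    """Full global+local fit of the million-death sample (shared: it is the
    most expensive single computation in the suite)."""
    return mm.fit(big_counts, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
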