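import numpy as np
import pytest

from connectopy import default_parcellation, simulate_cohort, SimulationConfig
from connectopy.simulate import fixture_suite


@pytest.fixture(scope="session")
def graphs():
    """Deterministic library of small weighted graphs."""
    return fixture_suite()


@pytest.fixture(scope="session")
def parcellation72():
    return default_parcellation()


@pytest.fixture(scope="session")
def small_cohort():
    """A 5+5 subject cohort on 8+8 nodes, with a right-hemisphere deficit."""
    cfg = SimulationConfig(
        n_nodes_per_hemisphere=8, n_controls=5, n_patients=5,
        delta=0.4, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """An exchangeable (delta=0) cohort on 8+8 nodes."""
    cfg = SimulationConfig(
        n_nodes_per_hemisphere=8, n_controls=5, n_patients=5,
        delta=0.0, seed=43,
    )
    return simulate_cohort(cfg)


def random_symmetric(n, seed, density=0.5, wmin=0.2, wmax=2.0):
    """Seeded random weighted undirected graph as a dense matrix."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w[iu[present], ju[present]] = rng.uniform(wmin, wmax, size=present.sum())
    return w + w.T
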