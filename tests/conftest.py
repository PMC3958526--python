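import numpy as np
import pytest

from mescnet import reference_parameters
from mescnet.sde import simulate_population
from mescnet.state_analysis import basin_boundary


@pytest.fixture(scope="session")
def ref():
    """Calibrated LIF/serum reference parameter set (p = 15, Y = 0)."""
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_2i(ref):
    return ref.replace(p=0.0)


@pytest.fixture(scope="session")
def boundary(ref):
    return basin_boundary(ref)


@pytest.fixture(scope="session")
def pop3d(ref):
    """1000 LIF/serum cells, 3 in-silico days, dt 0.1 min, from the NH state.

    Shared by the snapshot-phenotype and transition-rate checks.
    """
    return simulate_population(
        ref, n_cells=1000, init_policy="at_NH", duration=4320.0, dt=0.1,
        master_seed=1, record_stride=10,
    )


@pytest.fixture(scope="session")
def small_pop(ref):
    """Cheap 3-day population for structural/invariant checks."""
    return simulate_population(
        ref, n_cells=150, init_policy=("mixed", 0.5), duration=4320.0, dt=0.2,
        master_seed=7, record_stride=50,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
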