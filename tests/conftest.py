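import numpy as np
import pytest

from ringtae import NetworkParams, SolverSettings


@pytest.fixture(scope="session")
def printed_params():
    """The fitted 256-unit parameter set (the package defaults)."""
    return NetworkParams()


@pytest.fixture(scope="session")
def small_params():
    """A 32-unit network for cheap oracle comparisons."""
    return NetworkParams(n_units=32)


@pytest.fixture(scope="session")
def solver():
    return SolverSettings()


@pytest.fixture
def rng():
    return np.random.default_rng(20190919)
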