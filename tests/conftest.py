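import numpy as np
import pytest

from cepkit.synthetic_data import SimConfig, default_generating_pspm, simulate_dataset


@pytest.fixture(scope="session")
def pspm():
    """The default sharp generating/scanning motif model."""
    return default_generating_pspm()


@pytest.fixture(scope="session")
def sim_result():
    """One default simulated dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
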