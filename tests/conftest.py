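import numpy as np
import pytest

import spikemesh as sm


@pytest.fixture(scope="session")
def small_net():
    """A 0.3%-scale microcircuit (232 neurons) used across modules."""
    return sm.generate_microcircuit(0.003, 0.003, seed=3)


@pytest.fixture(scope="session")
def small_raster(small_net):
    return sm.run_network(small_net, 2000, mode="fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
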