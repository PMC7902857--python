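import numpy as np
import pytest

from targetproj import Dense, init_network


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net():
    """4-3-2 tanh/sigmoid net, He-initialised, 23 parameters."""
    return init_network([4, Dense(3, "tanh"), Dense(2, "sigmoid")], seed=42)


@pytest.fixture
def tiny_batch(rng):
    return rng.normal(size=(6, 4))
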