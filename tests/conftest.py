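import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_symmetric_weights(rng):
    """Random nonnegative symmetric 6x6 adjacency with zero diagonal."""
    a = rng.uniform(0.0, 1.0, size=(6, 6))
    w = 0.5 * (a + a.T)
    np.fill_diagonal(w, 0.0)
    return w
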