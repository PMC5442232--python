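import numpy as np
import pytest

import ratenet as rn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def weak_pair():
    """Two linear units, symmetric weak instantaneous coupling |w| = 0.1."""
    units = [rn.UnitParams(tau=1.0, sigma=0.5) for _ in range(2)]
    return rn.Network(units, [0, 1], [1, 0], [-0.1, -0.1], [0.0, 0.0])


@pytest.fixture
def tanh_net():
    """Small random tanh network with instantaneous coupling."""
    return rn.build_tanh_random(20, g=0.5, seed=2, sigma=0.5)
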