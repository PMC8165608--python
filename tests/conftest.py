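import numpy as np
import pytest

from eqprop import LayerSpec, build_mlff, initialize_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net(rng):
    """A 3-5-4-2 MLFF network with Glorot-initialized weights."""
    topo = build_mlff(LayerSpec((3, 5, 4, 2)))
    params = initialize_parameters(topo, rng)
    return topo, params


@pytest.fixture
def tiny_batch(rng):
    """Four inputs in (0,1)^3 with random one-hot 2-class targets."""
    X = rng.uniform(0.1, 0.9, (4, 3))
    Y = np.eye(2)[rng.integers(0, 2, 4)]
    return X, Y
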