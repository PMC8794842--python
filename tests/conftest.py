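import numpy as np
import pytest

from snnloop import NetworkWeights


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_net(rng):
    """A small feed-forward net plus sparse random input spikes."""
    C, H, O, T, B = 8, 6, 3, 40, 3
    weights = NetworkWeights(
        rng.normal(0, 0.25, (H, C)), rng.normal(0, 0.5, (O, H))
    )
    x = (rng.random((B, T, C)) < 0.08).astype(float)
    y = rng.integers(0, O, B)
    return weights, x, y


@pytest.fixture
def recurrent_net(rng):
    C, H, O, T, B = 10, 8, 3, 50, 4
    weights = NetworkWeights(
        rng.normal(0, 0.3, (H, C)),
        rng.normal(0, 0.5, (O, H)),
        rng.normal(0, 0.2, (H, H)),
    )
    x = (rng.random((B, T, C)) < 0.05).astype(float)
    return weights, x
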