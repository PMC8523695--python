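import numpy as np
import pytest

from fracgate import ChannelParams, UniformGrid
from fracgate.landscapes import quadratic


@pytest.fixture
def harmonic():
    """Unit harmonic well: the linear-relaxation benchmark landscape."""
    return quadratic(kappa=1.0)


@pytest.fixture
def channel_params():
    """A mildly depolarized channel ensemble (bias = 0.5, n = 4)."""
    return ChannelParams(n=4, eps1=1.0, eps2=3.0, z=1, beta=1.0, V=2.5)


@pytest.fixture
def fine_grid():
    return UniformGrid(dt=1e-3, n_steps=5000)


def total_variation(p, q):
    return 0.5 * float(np.sum(np.abs(np.asarray(p) - np.asarray(q))))
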