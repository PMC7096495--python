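import numpy as np
import pytest

from mrilnet.params import SimParams, LearningParams, StdpParams


@pytest.fixture
def params():
    return SimParams(n_in=20, n_out=3, t0=500.0)


@pytest.fixture
def lp():
    return LearningParams(eta=1e-4, gamma=0.5)


@pytest.fixture
def sp():
    return StdpParams(gmax=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
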