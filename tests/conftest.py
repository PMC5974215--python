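import numpy as np
import pytest

from stbp import LIFConfig, SurrogateSpec, parse_architecture


@pytest.fixture
def mnist_like_cfg():
    """The tabulated static-image configuration (threshold 1.5, decay 0.1)."""
    return LIFConfig(tau=0.1, v_th=1.5, dt=1.0, T=30)


@pytest.fixture
def small_cfg():
    """A short-window configuration for fast unit tests."""
    return LIFConfig(tau=0.1, v_th=1.5, T=5)


@pytest.fixture
def dense_chain():
    return parse_architecture("4-6-3")


@pytest.fixture
def conv_chain():
    return parse_architecture("6x6x1-2C3-P2-3")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
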