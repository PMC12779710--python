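import numpy as np
import pytest

from pushpull.config import ALIFParams, ChannelProfile, NetworkConfig
from pushpull.network import initialize_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return ALIFParams()


@pytest.fixture
def tiny_config():
    """Small but structurally faithful network for fast tests."""
    return NetworkConfig(n_e=24, n_i=6, n_channels=4, seed=0)


@pytest.fixture
def tiny_network(tiny_config, rng):
    return initialize_network(tiny_config, rng)


@pytest.fixture
def default_network(rng):
    return initialize_network(NetworkConfig(), rng)


@pytest.fixture
def short_profile():
    """Five-block trial geometry for fast task tests."""
    return ChannelProfile(n_blocks=5, change_t_min=68, change_t_max=272)
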