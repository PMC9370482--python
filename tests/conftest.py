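import numpy as np
import pytest

from mechanoindent import ProtocolConfig, build_train, depth_map
from mechanoindent.synthetic_data import TraceGenConfig


@pytest.fixture(scope="session")
def default_train():
    """Canonical six-step train: D = 8..18 um in 2 um increments."""
    return build_train(ProtocolConfig())


@pytest.fixture(scope="session")
def default_depths(default_train):
    """Depths for a group with <T_max> = 9.2 um."""
    return depth_map(default_train, 9.2)


@pytest.fixture(scope="session")
def trace_config():
    return TraceGenConfig()


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free generator without spontaneous excursions."""
    return TraceGenConfig(noise_cv=0.0, spontaneous_prob=0.0)
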