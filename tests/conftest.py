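import math

import numpy as np
import pytest

from dorsalflow.network import NetworkConfig, assemble


@pytest.fixture(scope="session")
def default_config():
    return NetworkConfig()


@pytest.fixture(scope="session")
def default_network(default_config):
    """One assembled network shared by the structural and end-to-end tests."""
    return assemble(default_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
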