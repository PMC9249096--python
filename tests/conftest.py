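import numpy as np
import pytest

from achnet.network import NetworkConfig, build_network


@pytest.fixture(scope="session")
def small_topology():
    """A 40-neuron oriented scale-free topology used across tests."""
    return build_network(NetworkConfig(n=40, z_passes=4, p_in=0.5, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
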