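import numpy as np
import pytest

from richconn.netbuild import WeightedNetwork
from richconn.synthgen import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Compact cohort used where full study scale is unnecessary."""
    return SimulationConfig(
        n_nodes=40, n_hubs=14, n_group1=12, n_group2=12, clinical_couplings=(), seed=7
    )


def make_network(weights) -> WeightedNetwork:
    w = np.asarray(weights, dtype=float)
    return WeightedNetwork(w)


def network_from_edges(n, edges) -> WeightedNetwork:
    """edges: dict {(i, j): weight}."""
    w = np.zeros((n, n))
    for (i, j), v in edges.items():
        w[i, j] = w[j, i] = v
    return WeightedNetwork(w)


@pytest.fixture
def network_factory():
    return network_from_edges
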