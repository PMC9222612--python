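import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from coopdom.networks import Layer, MultilayerNetwork


@pytest.fixture
def triangle_layer():
    return Layer(nx.cycle_graph(3))


@pytest.fixture
def star_layer():
    """K_{1,4}: node 0 is the hub, 1..4 the leaves."""
    return Layer(nx.star_graph(4))


@pytest.fixture
def two_node_layer():
    g = nx.Graph()
    g.add_edge(0, 1)
    return Layer(g)


def make_multilayer(n_layers: int, n_nodes: int, seed: int = 0) -> MultilayerNetwork:
    """Stack of small identical-size random layers for dynamics tests."""
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(n_layers):
        g = nx.gnp_random_graph(n_nodes, 0.4, seed=int(rng.integers(2**31)))
        layers.append(Layer(g))
    return MultilayerNetwork(layers)
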