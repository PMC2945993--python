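import networkx as nx
import pytest

from helpers import graph_from_nx


@pytest.fixture
def path4():
    return graph_from_nx(nx.path_graph(4), "P4")


@pytest.fixture
def star13():
    return graph_from_nx(nx.star_graph(3), "K13")


@pytest.fixture
def triangle():
    return graph_from_nx(nx.cycle_graph(3), "C3")


@pytest.fixture(scope="session")
def toy_fig2():
    """Six-reaction toy pathway: a hexagon-like network R1..R6."""
    g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)])
    return graph_from_nx(g, "toy")
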