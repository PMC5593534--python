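import networkx as nx
import pytest


@pytest.fixture
def triangle():
    return nx.complete_graph(3)


@pytest.fixture
def star5():
    """Star with center 0 and five leaves."""
    return nx.star_graph(5)


@pytest.fixture
def path3():
    return nx.path_graph(3)


@pytest.fixture(scope="session")
def atlas_connected():
    """Every connected graph on at most 7 nodes (graph atlas, exhaustive)."""
    from networkx.generators.atlas import graph_atlas_g

    return [g for g in graph_atlas_g() if g.number_of_nodes() >= 1 and nx.is_connected(g)]
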