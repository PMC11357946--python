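import itertools

import networkx as nx
import pytest


@pytest.fixture
def path5():
    """Path graph a-b-c-d-e used in the worked distance examples."""
    return nx.path_graph(["a", "b", "c", "d", "e"])


@pytest.fixture
def two_triangles():
    """Two triangles joined by one bridge edge (7 edges)."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture
def two_cliques():
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    g.add_edges_from(itertools.combinations(range(4), 2))
    g.add_edges_from(itertools.combinations(range(4, 8), 2))
    g.add_edge(3, 4)
    return g
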