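import networkx as nx
import pytest

from netged import AlignedPair


def graph_from_edges(nodes, edges, vocabulary="test"):
    g = nx.Graph(vocabulary=vocabulary)
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            u, v, w = e
        else:
            (u, v), w = e, 1.0
        g.add_edge(u, v, weight=w)
    return g


@pytest.fixture
def toy_pair():
    """G1 = {ab, bc}, G2 = {ab, cd} on nodes {a, b, c, d}."""
    g1 = graph_from_edges("abcd", [("a", "b"), ("b", "c")])
    g2 = graph_from_edges("abcd", [("a", "b"), ("c", "d")])
    return AlignedPair(g1, g2)


@pytest.fixture
def star_pair():
    """Identical 4-node stars; the degree sequence forces the edge set."""
    g1 = graph_from_edges("abcd", [("a", "b"), ("a", "c"), ("a", "d")])
    return AlignedPair(g1, g1.copy())


def six_cycle():
    return graph_from_edges("123456", [("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "6"), ("6", "1")])


def two_triangles():
    return graph_from_edges("123456", [("1", "2"), ("2", "3"), ("1", "3"), ("4", "5"), ("5", "6"), ("4", "6")])
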