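import networkx as nx
import numpy as np
import pytest

from netprior.network import InteractionNetwork


def nx_to_net(g: nx.Graph) -> InteractionNetwork:
    """Convert a networkx graph to an InteractionNetwork with string ids."""
    net = InteractionNetwork(nodes=(f"n{i}" for i in sorted(g.nodes())))
    for u, v in g.edges():
        net.add_edge(f"n{u}", f"n{v}")
    return net


def random_net(n: int, p: float, seed: int) -> InteractionNetwork:
    return nx_to_net(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def path_net() -> InteractionNetwork:
    """Path A-B-C."""
    return InteractionNetwork(edges=[("A", "B"), ("B", "C")])


@pytest.fixture
def six_node_net() -> InteractionNetwork:
    """Connected 6-node fixture with a triangle, a tail and a leaf."""
    edges = [("A", "B"), ("B", "C"), ("A", "C"), ("C", "D"), ("D", "E"),
             ("E", "F"), ("B", "E")]
    return InteractionNetwork(edges=edges)
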