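import random

import networkx as nx
import pytest

from modscape import EvidenceNetwork


def random_evidence_network(
    n_nodes: int, p: float, seed: int, evidence_rng: bool = True
) -> EvidenceNetwork:
    """A seeded Erdos–Renyi network whose edges carry random evidence sets."""
    rng = random.Random(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    net = EvidenceNetwork()
    for node in g.nodes:
        net.add_node(f"p{node:03d}")
    choices = [
        {"neighbourhood"},
        {"profile"},
        {"neighbourhood", "profile"},
    ]
    for a, b in g.edges:
        ev = rng.choice(choices) if evidence_rng else {"profile"}
        net.add_edge(f"p{a:03d}", f"p{b:03d}", ev)
    return net


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g
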