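import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def path_graph_ab():
    """Two-node path with z_A = 1, z_B = 3 (hand-traceable greedy example)."""
    g = nx.Graph()
    g.add_edge("A", "B")
    nx.set_node_attributes(g, {"A": 1.0, "B": 3.0}, "z")
    nx.set_node_attributes(g, {"A": 0.16, "B": 0.001}, "p_g")
    return g


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """A random connected graph with standard normal node weights."""
    n = int(rng.integers(2, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, float(rng.uniform(0.3, 0.9)), seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
    z = {node: float(rng.normal()) for node in g}
    nx.set_node_attributes(g, z, "z")
    return g
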