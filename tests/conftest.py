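import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for the oracles module


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def two_triangles():
    """Two disjoint triangles: the reference modularity fixture (Q = 0.5)."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


def random_graph(rng, n_max=7, n_min=2, p=None):
    """A random Erdos-Renyi-style simple graph with at least one edge."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        prob = p if p is not None else rng.uniform(0.25, 0.9)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for u in range(n):
            for v in range(u + 1, n):
                if rng.random() < prob:
                    g.add_edge(u, v)
        if g.number_of_edges() > 0:
            return g
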