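"""Per-graph topology metrics.

Standard descriptors of a vascular graph: node/edge counts, average
degree, clustering coefficient, betweenness centrality, density, hop-count
diameter and average path length, and the degree distribution.

Except for the raw counts and average degree, metrics are computed on the
simple unweighted projection of the multigraph (parallel edges collapsed,
self-loops dropped): local clustering is 2*T(v)/(deg(v)*(deg(v)-1)) with 0
for degree < 2; betweenness is the pair-dependency sum normalised by
(N-1)(N-2)/2 with endpoints excluded; density is 2E/(N(N-1)); diameter and
average path length use hop-count shortest paths on the largest connected
component (the component count is reported alongside).  Average degree is
2E/N on the full multigraph, a self-loop contributing 2 to its node's
degree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["NetMetrics", "basic_metrics", "degree_distribution", "simple_projection"]


@dataclass(frozen=True)
class NetMetrics:
    """Topology record of one vascular graph."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_betweenness: float
    density: float
    diameter: int
    avg_path_len: float
    n_components: int
    degree_hist: dict[int, int] = field(default_factory=dict)
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "avg_clustering": self.avg_clustering,
            "avg_betweenness": self.avg_betweenness,
            "density": self.density,
            "diameter": self.diameter,
            "avg_path_len": self.avg_path_len,
            "n_components": self.n_components,
        }


def simple_projection(g: nx.Graph) -> nx.Graph:
    """Simple unweighted view: parallel edges collapsed, self-loops dropped."""
    s = nx.Graph()
    s.add_nodes_from(g.nodes)
    s.add_edges_from((u, v) for u, v in g.edges() if u != v)
    return s


def basic_metrics(g: nx.Graph) -> NetMetrics:
    """Compute the full topology record of a graph.

    Graphs with fewer than two nodes are degenerate: density and
    betweenness are reported as 0 with the ``degenerate`` flag set.  An
    empty graph is an error.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("metrics undefined for the empty graph")
    e_multi = g.number_of_edges()
    s = simple_projection(g)
    degenerate = n < 2

    avg_clust = sum(nx.clustering(s).values()) / n
    if degenerate:
        avg_btw, density = 0.0, 0.0
    else:
        avg_btw = sum(nx.betweenness_centrality(s, normalized=True).values()) / n
        density = nx.density(s)

    comps = list(nx.connected_components(s))
    lcc = s.subgraph(max(comps, key=lambda c: (len(c), sorted(c))))
    if lcc.number_of_nodes() < 2:
        diameter, avg_path = 0, 0.0
    else:
        diameter = nx.diameter(lcc)
        avg_path = nx.average_shortest_path_length(lcc)

    return NetMetrics(
        n_nodes=n,
        n_edges=e_multi,
        avg_degree=2.0 * e_multi / n,
        avg_clustering=avg_clust,
        avg_betweenness=avg_btw,
        density=density,
        diameter=int(diameter),
        avg_path_len=float(avg_path),
        n_components=len(comps),
        degree_hist=degree_distribution(g),
        degenerate=degenerate,
    )


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Histogram degree -> node count over the simple projection.

    Satisfies sum(counts) = N and sum(degree * count) = 2E of the
    projection (handshake identity).
    """
    s = simple_projection(g)
    return dict(sorted(Counter(d for _, d in s.degree()).items()))
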