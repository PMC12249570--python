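"""Skeleton-to-graph conversion.

A skeleton is converted into an undirected weighted vascular graph:
nodes are bifurcations (merged junction clusters) and terminal endpoints,
edges are vessel segments traced along the centerline between them.  Each
edge carries two lengths:

* ``weight`` — the Euclidean chord between the two node coordinates (the
  default edge weight of the analysis);
* ``path_len`` — the along-skeleton arc length of the traced segment.

Chord <= arc, so ``weight <= path_len`` on every edge.  Parallel edges and
self-loops are legitimate (vessel loops) and kept; the graph container is a
:class:`networkx.MultiGraph` with node attributes ``row``, ``col``,
``kind`` (``junction`` / ``endpoint`` / ``anchor``) and edge attributes
``weight`` and ``path_len``.  Coordinates are (row, col), 0-based, origin
top-left.

A connected skeleton component with no junction or endpoint (a pure cycle)
is represented by one ``anchor`` node carrying a self-loop whose
``path_len`` is the cycle perimeter; an isolated skeleton pixel becomes an
edgeless endpoint node.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import ndimage

from .vesselquant import Skeleton, node_clusters, skeleton_length, _neighbor_counts

__all__ = [
    "skeleton_to_graph",
    "to_adjacency",
    "simplify",
    "write_graphml",
    "write_edgelist",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _dist(p: tuple[int, int], q: tuple[int, int]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def _neighbors8(p: tuple[int, int], mask: np.ndarray) -> list[tuple[int, int]]:
    r, c = p
    h, w = mask.shape
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                out.append((rr, cc))
    return out


def skeleton_to_graph(sk: Skeleton) -> nx.MultiGraph:
    """Trace a skeleton into a vascular multigraph.

    Every skeleton pixel is accounted for exactly once: node-cluster pixels
    anchor the nodes, and each remaining centerline pixel belongs to exactly
    one traced edge.  Tracing marches from each node-cluster pixel along
    unvisited skeleton pixels until the next node cluster, accumulating
    step-weighted arc length (1 orthogonal, sqrt(2) diagonal).
    """
    mask = sk.mask
    scale = sk.scale
    g = nx.MultiGraph()
    junctions, endpoints = node_clusters(sk)

    node_of: dict[tuple[int, int], int] = {}
    coord: dict[int, tuple[int, int]] = {}
    nid = 0
    for centroid, pixels in junctions:
        g.add_node(nid, row=centroid[0], col=centroid[1], kind="junction")
        coord[nid] = centroid
        for p in pixels:
            node_of[p] = nid
        nid += 1
    for p in endpoints:
        g.add_node(nid, row=p[0], col=p[1], kind="endpoint")
        coord[nid] = p
        node_of[p] = nid
        nid += 1

    # isolated pixels (no neighbours at all) become edgeless endpoints
    nb = _neighbor_counts(mask)
    for p in map(tuple, np.argwhere(mask & (nb == 0))):
        g.add_node(nid, row=p[0], col=p[1], kind="endpoint")
        coord[nid] = p
        node_of[p] = nid
        nid += 1

    visited: set[tuple[int, int]] = set()
    direct_pairs: set[frozenset] = set()

    def add_edge(u: int, v: int, path_len: float) -> None:
        w = _dist(coord[u], coord[v]) * scale
        # discretization guard: cluster centroids can sit a fraction of a
        # pixel beyond the traced pixels; arc is never shorter than chord
        g.add_edge(u, v, weight=w, path_len=max(path_len * scale, w))

    def trace(start_node: int, p: tuple[int, int], q: tuple[int, int]) -> None:
        path_len = _dist(p, q)
        visited.add(q)
        prev, cur = p, q
        n_free = 1
        while True:
            nbrs = _neighbors8(cur, mask)
            term = [
                t for t in nbrs
                if t in node_of and t != prev
                and (node_of[t] != start_node or n_free >= 2)
            ]
            if term:
                t = min(term)
                add_edge(start_node, node_of[t], path_len + _dist(cur, t))
                return
            nxt = [t for t in nbrs if t not in node_of and t not in visited]
            if not nxt:
                # degenerate spur end (should not occur on a clean skeleton):
                # close it with an endpoint node at the current pixel
                nonlocal_nid = g.number_of_nodes()
                g.add_node(nonlocal_nid, row=cur[0], col=cur[1], kind="endpoint")
                coord[nonlocal_nid] = cur
                node_of[cur] = nonlocal_nid
                add_edge(start_node, nonlocal_nid, path_len)
                return
            t = min(nxt)
            path_len += _dist(cur, t)
            visited.add(t)
            prev, cur = cur, t
            n_free += 1

    for p in sorted(node_of):
        u = node_of[p]
        for t in _neighbors8(p, mask):
            if t in node_of:
                if node_of[t] != u:
                    pair = frozenset((p, t))
                    if pair not in direct_pairs:
                        direct_pairs.add(pair)
                        add_edge(u, node_of[t], _dist(p, t))
            elif t not in visited:
                trace(u, p, t)

    # pure cycles: remaining centerline pixels in components without nodes
    free = mask.copy()
    for p in node_of:
        free[p] = False
    for p in visited:
        free[p] = False
    if free.any():
        labels, n = ndimage.label(free, structure=_STRUCT8)
        for lab in range(1, n + 1):
            comp = labels == lab
            p = tuple(np.argwhere(comp)[0])
            anchor = g.number_of_nodes()
            g.add_node(anchor, row=int(p[0]), col=int(p[1]), kind="anchor")
            coord[anchor] = (int(p[0]), int(p[1]))
            sub = Skeleton(comp, sk.parent)
            g.add_edge(anchor, anchor, weight=0.0, path_len=skeleton_length(sub))
    return g


def to_adjacency(g: nx.MultiGraph) -> np.ndarray:
    """Weighted adjacency matrix of a vascular graph.

    Rows/columns follow sorted node order; symmetric; a parallel-edge pair
    contributes its minimum weight; the diagonal holds self-loop weights
    (0 where there is none).
    """
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    for u, v, data in g.edges(data=True):
        i, j = index[u], index[v]
        w = data["weight"]
        if seen[i, j]:
            w = min(w, a[i, j])
        a[i, j] = a[j, i] = w
        seen[i, j] = seen[j, i] = True
    return a


def simplify(g: nx.MultiGraph) -> nx.MultiGraph:
    """Contract chains of degree-2 non-anchor nodes.

    Each maximal chain of degree-2 intermediate nodes is replaced by a
    single edge whose ``path_len`` is the sum of the constituent arcs and
    whose ``weight`` is the Euclidean chord between the surviving end
    nodes.  Surviving nodes keep their kinds.  Idempotent.
    """
    h = g.copy()
    changed = True
    while changed:
        changed = False
        for v in sorted(h.nodes):
            if h.nodes[v].get("kind") == "anchor":
                continue
            if h.degree(v) != 2:
                continue
            inc = list(h.edges(v, keys=True, data=True))
            if len(inc) != 2:        # a self-loop contributes one edge of degree 2
                continue
            d1, d2 = inc[0][3], inc[1][3]
            u = inc[0][1] if inc[0][0] == v else inc[0][0]
            w = inc[1][1] if inc[1][0] == v else inc[1][0]
            if u == v or w == v:
                continue             # self-loop: leave cycles alone
            path_len = d1["path_len"] + d2["path_len"]
            h.remove_node(v)
            if u == w:
                h.add_edge(u, w, weight=0.0, path_len=path_len)
            else:
                cu = (h.nodes[u]["row"], h.nodes[u]["col"])
                cw = (h.nodes[w]["row"], h.nodes[w]["col"])
                h.add_edge(u, w, weight=_dist(cu, cw), path_len=path_len)
            changed = True
            break
    return h


def write_graphml(g: nx.MultiGraph, path: str | Path) -> None:
    """GraphML export (node attrs row/col/kind, edge attrs weight/path_len)."""
    nx.write_graphml(g, str(path))


def write_edgelist(g: nx.MultiGraph, path: str | Path) -> None:
    """Three-column weighted edge list (u, v, weight), tab-separated."""
    with open(path, "w") as fh:
        fh.write("# u\tv\tweight\n")
        for u, v, data in g.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['weight']:.6g}\n")
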