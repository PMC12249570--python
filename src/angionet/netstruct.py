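"""Structural network analyses: modularity, communities, fractal
dimension, robustness.

These are the "custom-script" analyses of the vascular-network workflow
and are authored here rather than delegated:

* Newman modularity ``Q = sum_c [ e_c/m - (d_c/2m)^2 ]`` of a node
  partition, on the simple unweighted projection of the graph;
* greedy agglomerative modularity maximisation (CNM-style): start from
  singleton communities and repeatedly merge the connected pair with the
  largest positive delta-Q, deterministic tie-break by smallest community
  id pair;
* box-counting fractal dimension: least-squares slope of log N(r) versus
  log(1/r) over grid-aligned dyadic box sizes, where N(r) counts r-by-r
  boxes containing foreground;
* robustness-to-removal curves: largest-connected-component fraction as a
  nested sequence of nodes is deleted, either uniformly at random (mean
  over replicates) or targeted by static degree / betweenness rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .netmetrics import simple_projection
from .synthgrowth import VascularImage
from .vesselquant import Skeleton

__all__ = [
    "Partition",
    "FractalFit",
    "RobustnessCurve",
    "modularity",
    "detect_communities",
    "fractal_dimension",
    "robustness",
]


# ---------------------------------------------------------------------------
# Modularity and community detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Partition:
    """A node partition with its modularity and per-community statistics.

    ``community_stats[c]`` holds ``size``, ``avg_degree_centrality``
    (mean deg/(N-1) over members) and ``avg_edge_weight`` (mean weight of
    edges incident to members) for community ``c``.
    """

    assignment: dict
    q: float
    n_communities: int
    community_stats: dict = field(default_factory=dict)


def modularity(g: nx.Graph, assignment: Mapping) -> float:
    """Newman modularity Q of a partition on the simple projection.

    Q = sum over communities c of [ e_c/m - (d_c/2m)^2 ] with m the edge
    count, e_c the intra-community edge count and d_c the summed degree of
    c.  A one-community partition scores exactly 0; -0.5 <= Q <= 1.
    """
    s = simple_projection(g)
    missing = set(s.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)[:5]}")
    m = s.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    e_c: dict = {}
    d_c: dict = {}
    for u, v in s.edges():
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e_c[cu] = e_c.get(cu, 0) + 1
    for v, deg in s.degree():
        c = assignment[v]
        d_c[c] = d_c.get(c, 0) + deg
    return float(
        sum(e_c.get(c, 0) / m - (d_c[c] / (2.0 * m)) ** 2 for c in d_c)
    )


def detect_communities(g: nx.Graph) -> Partition:
    """Greedy agglomerative modularity maximisation (CNM-style).

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest delta-Q until no merge increases Q.  Ties are
    broken deterministically by the smallest (community id, community id)
    pair, so the result is reproducible.  Edge weights are ignored for the
    merge criterion (unweighted Q) but enter the per-community mean
    incident edge weight statistic.
    """
    s = simple_projection(g)
    m = s.number_of_edges()
    if m == 0:
        raise ValueError("community detection undefined for an edgeless graph")

    comm_of = {v: i for i, v in enumerate(sorted(s.nodes))}
    members = {i: {v} for v, i in comm_of.items()}
    deg_sum = {i: s.degree(v) for v, i in comm_of.items()}
    e_between: dict[frozenset, int] = {}
    for u, v in s.edges():
        key = frozenset((comm_of[u], comm_of[v]))
        if len(key) == 2:
            e_between[key] = e_between.get(key, 0) + 1

    two_m = 2.0 * m
    while True:
        best = None
        for key, e_ab in e_between.items():
            a, b = sorted(key)
            dq = e_ab / m - 2.0 * (deg_sum[a] / two_m) * (deg_sum[b] / two_m)
            if dq <= 1e-15:
                continue
            cand = (dq, -a, -b)
            if best is None or cand > best[0]:
                best = (cand, a, b)
        if best is None:
            break
        _, a, b = best
        # merge b into a
        members[a] |= members.pop(b)
        deg_sum[a] += deg_sum.pop(b)
        new_between: dict[frozenset, int] = {}
        for key, cnt in e_between.items():
            if b in key:
                other = (key - {b}) or {a}
                key = frozenset({a, next(iter(other))})
                if len(key) == 1:
                    continue
            new_between[key] = new_between.get(key, 0) + cnt
        e_between = new_between

    # relabel communities 0..k-1 by smallest member node
    order = sorted(members.values(), key=lambda nodes: min(nodes))
    assignment = {v: c for c, nodes in enumerate(order) for v in nodes}
    q = modularity(g, assignment)

    n = s.number_of_nodes()
    stats = {}
    for c, nodes in enumerate(order):
        degs = [s.degree(v) for v in nodes]
        inc_w = [
            d.get("weight", 1.0)
            for u, v, d in g.edges(data=True)
            if (u in nodes or v in nodes)
        ]
        stats[c] = {
            "size": len(nodes),
            "avg_degree_centrality": (
                float(np.mean(degs)) / (n - 1) if n > 1 else 0.0
            ),
            "avg_edge_weight": float(np.mean(inc_w)) if inc_w else 0.0,
        }
    return Partition(assignment=assignment, q=q,
                     n_communities=len(order), community_stats=stats)


# ---------------------------------------------------------------------------
# Fractal dimension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FractalFit:
    """Box-counting fit: occupied-box counts N(r) and the log-log slope."""

    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    d: float
    r2: float


def _box_count(mask: np.ndarray, r: int) -> int:
    h, w = mask.shape
    ph, pw = (-h) % r, (-w) % r
    m = np.pad(mask, ((0, ph), (0, pw)))
    blocks = m.reshape(m.shape[0] // r, r, m.shape[1] // r, r)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(
    img: VascularImage | Skeleton | np.ndarray,
    box_sizes: Sequence[int] | None = None,
) -> FractalFit:
    """Box-counting fractal dimension of a binary mask.

    N(r) counts grid-aligned r-by-r boxes (anchored at the origin, no
    offset averaging) containing at least one foreground pixel; ``d`` is
    the least-squares slope of log N(r) versus log(1/r) and ``r2`` the
    coefficient of determination of that fit.  Defaults to dyadic box
    sizes 2, 4, ..., side/4; at least four sizes are required.

    For network-complexity analysis the mask is conventionally the
    skeleton (pass a :class:`Skeleton`); passing the full vessel mask
    measures the area-covering object instead.
    """
    if isinstance(img, Skeleton):
        mask = img.mask
    elif isinstance(img, VascularImage):
        mask = img.mask
    else:
        mask = np.asarray(img, dtype=bool)
    if not mask.any():
        raise ValueError("fractal dimension undefined for an empty mask")
    if box_sizes is None:
        side = min(mask.shape)
        box_sizes = []
        r = 2
        while r <= side // 4:
            box_sizes.append(r)
            r *= 2
    sizes = sorted(int(r) for r in box_sizes)
    if len(sizes) < 4:
        raise ValueError("need at least 4 box sizes for a stable fit")
    counts = [_box_count(mask, r) for r in sizes]
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return FractalFit(tuple(sizes), tuple(counts), float(slope), r2)


# ---------------------------------------------------------------------------
# Robustness to node removal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RobustnessCurve:
    """Largest-component survival under nested node removal."""

    strategy: str
    fractions: tuple[float, ...]
    lcc_frac: tuple[float, ...]          # mean over replicates
    replicates: tuple[tuple[float, ...], ...] = ()


def _lcc_size(s: nx.Graph) -> int:
    if s.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(s))


def robustness(
    g: nx.Graph,
    strategy: str = "random",
    fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    reps: int = 20,
    rng_seed: int | None = None,
) -> RobustnessCurve:
    """Largest-connected-component fraction under nested node removal.

    Per replicate a full removal order is drawn once (uniform shuffle for
    ``random``; descending static degree or betweenness, ties by node id,
    for the targeted strategies, which are deterministic and use one
    replicate).  At fraction f the first floor(f*N) nodes of that order
    are removed and the surviving largest-component size is divided by the
    original N; nested removals make each replicate's curve non-increasing
    by construction.
    """
    s = simple_projection(g)
    n = s.number_of_nodes()
    if n < 2:
        raise ValueError("robustness needs at least 2 nodes")
    fr = [float(f) for f in fractions]
    if any(f < 0 or f > 1 for f in fr) or sorted(fr) != fr:
        raise ValueError("fractions must be sorted ascending within [0, 1]")

    nodes_sorted = sorted(s.nodes)
    if strategy == "random":
        if reps < 1:
            raise ValueError("random strategy needs reps >= 1")
        rng = np.random.default_rng(rng_seed)
        orders = [
            [nodes_sorted[i] for i in rng.permutation(n)] for _ in range(reps)
        ]
    elif strategy == "degree_targeted":
        orders = [sorted(nodes_sorted, key=lambda v: (-s.degree(v), v))]
    elif strategy == "betweenness_targeted":
        btw = nx.betweenness_centrality(s, normalized=True)
        orders = [sorted(nodes_sorted, key=lambda v: (-btw[v], v))]
    else:
        raise ValueError(
            "strategy must be random, degree_targeted or betweenness_targeted"
        )

    curves = []
    for order in orders:
        curve = []
        for f in fr:
            k = int(math.floor(f * n))
            surv = s.copy()
            surv.remove_nodes_from(order[:k])
            curve.append(_lcc_size(surv) / n)
        curves.append(tuple(curve))
    mean_curve = tuple(float(np.mean(col)) for col in zip(*curves))
    return RobustnessCurve(strategy, tuple(fr), mean_curve, tuple(curves))
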