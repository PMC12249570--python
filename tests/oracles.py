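"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation — and shares no code path with the library
implementations it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def adjacency_sets(edges, nodes):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    return adj


def brute_clustering(edges, nodes):
    """Local clustering by exhaustive neighbour-pair counting."""
    adj = adjacency_sets(edges, nodes)
    out = {}
    for v in nodes:
        nb = adj[v]
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        tri = sum(1 for a, b in combinations(sorted(nb), 2) if b in adj[a])
        out[v] = 2.0 * tri / (k * (k - 1))
    return out


def _bfs_dist(adj, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def _all_shortest_paths(adj, s, t, dist):
    """Enumerate every shortest s-t path by descending-distance DFS."""
    paths = []
    stack = [[t]]
    while stack:
        path = stack.pop()
        head = path[-1]
        if head == s:
            paths.append(path[::-1])
            continue
        for w in adj[head]:
            if dist.get(w, -1) == dist[head] - 1:
                stack.append(path + [w])
    return paths


def brute_betweenness(edges, nodes):
    """Normalized betweenness by explicit shortest-path enumeration.

    Pair-dependency sum over all unordered pairs (endpoints excluded),
    divided by (N-1)(N-2)/2.
    """
    adj = adjacency_sets(edges, nodes)
    n = len(nodes)
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        dist = _bfs_dist(adj, s)
        if t not in dist:
            continue
        paths = _all_shortest_paths(adj, s, t, dist)
        sigma = len(paths)
        for v in nodes:
            if v == s or v == t:
                continue
            cnt = sum(1 for p in paths if v in p)
            btw[v] += cnt / sigma
    if n > 2:
        norm = (n - 1) * (n - 2) / 2.0
        btw = {v: b / norm for v, b in btw.items()}
    return btw


def brute_paths(edges, nodes):
    """(diameter, average path length) of the largest component, by BFS."""
    adj = adjacency_sets(edges, nodes)
    comps = []
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        comp = set(_bfs_dist(adj, v))
        seen |= comp
        comps.append(comp)
    lcc = max(comps, key=lambda c: (len(c), sorted(c)))
    if len(lcc) < 2:
        return 0, 0.0
    dists = []
    for s, t in combinations(sorted(lcc), 2):
        dists.append(_bfs_dist(adj, s)[t])
    return max(dists), sum(dists) / len(dists)


def pairwise_modularity(edges, nodes, assignment):
    """Q via the pairwise double sum (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta."""
    simple = {frozenset((u, v)) for u, v in edges if u != v}
    m = len(simple)
    adj = adjacency_sets(edges, nodes)
    k = {v: len(adj[v]) for v in nodes}
    two_m = 2.0 * m
    q = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            a_ij = 1.0 if frozenset((i, j)) in simple else 0.0
            q += a_ij - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def max_modularity(edges, nodes):
    """Exhaustive maximum of Q over all partitions (feasible for N <= 8)."""
    best = -1.0
    for part in set_partitions(sorted(nodes)):
        assignment = {v: i for i, block in enumerate(part) for v in block}
        q = pairwise_modularity(edges, nodes, assignment)
        best = max(best, q)
    return best
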