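"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the package: topology metrics come from explicit
BFS level-counting, survival statistics from the textbook formulas, and
hypergeometric tails from exhaustive enumeration of draws.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# graph topology
# ---------------------------------------------------------------------------


def bfs_dist_and_counts(adj: dict, source) -> tuple[dict, dict]:
    """Distances and number-of-shortest-paths from source via plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def brute_topology(edges: list[tuple], nodes: list) -> dict:
    """K, L, BC, CC for every node, from first principles.

    BC(v) = Σ over unordered pairs i<j (both ≠ v, within v's component) of
    σ_iv·σ_vj / σ_ij where the sum of path counts is taken only when
    d(i,v) + d(v,j) = d(i,j).
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {}
    sigma = {}
    for n in nodes:
        dist[n], sigma[n] = bfs_dist_and_counts(adj, n)
    out = {}
    for v in nodes:
        reach = [i for i in dist[v] if i != v]
        total = sum(dist[v][i] for i in reach)
        K = len(adj[v])
        L = total / len(reach)
        CC = len(reach) / total
        BC = 0.0
        for i, j in itertools.combinations(reach, 2):
            if dist[i][v] + dist[v][j] == dist[i][j]:
                BC += sigma[i][v] * sigma[v][j] / sigma[i][j]
        out[v] = {"K": K, "L": L, "BC": BC, "CC": CC}
    return out


def brute_edge_betweenness(edges: list[tuple], nodes: list) -> dict:
    """Edge betweenness from path counts: for each unordered node pair
    (i, j), an edge u–v carries σ_i(u)·σ_j(v)/σ_ij when it lies on a
    shortest i–j path (in either orientation)."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {}
    sigma = {}
    for n in nodes:
        dist[n], sigma[n] = bfs_dist_and_counts(adj, n)
    eb = {tuple(sorted(e)): 0.0 for e in edges}
    for i, j in itertools.combinations(nodes, 2):
        if j not in dist[i]:
            continue
        d_ij = dist[i][j]
        s_ij = sigma[i][j]
        for u, v in edges:
            count = 0
            if u in dist[i] and v in dist[j] and dist[i][u] + 1 + dist[j][v] == d_ij:
                count += sigma[i][u] * sigma[j][v]
            if v in dist[i] and u in dist[j] and dist[i][v] + 1 + dist[j][u] == d_ij:
                count += sigma[i][v] * sigma[j][u]
            if count:
                eb[tuple(sorted((u, v)))] += count / s_ij
    return eb


def components(edges: list[tuple], nodes: list) -> list[set]:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    out = []
    for n in nodes:
        if n in seen:
            continue
        comp = {n}
        queue = deque([n])
        while queue:
            x = queue.popleft()
            for w in adj[x]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        out.append(comp)
    return out


def brute_girvan_newman_best_q(edges: list[tuple], nodes: list) -> float:
    """Max modularity over all dendrogram levels of a from-scratch
    Girvan–Newman run (highest-betweenness edge removed each step, ties
    by lexicographic endpoint pair)."""
    all_edges = [tuple(sorted(e)) for e in edges]
    remaining = list(all_edges)
    best = partition_modularity(all_edges, components(remaining, nodes))
    while remaining:
        eb = brute_edge_betweenness(remaining, nodes)
        target = min(eb, key=lambda e: (-eb[e], e))
        remaining = [e for e in remaining if e != target]
        q = partition_modularity(all_edges, components(remaining, nodes))
        best = max(best, q)
    return best


def partition_modularity(edges: list[tuple], partition: list[set]) -> float:
    """Newman–Girvan modularity Q computed from the definition."""
    m = len(edges)
    degree: dict = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    q = 0.0
    for comm in partition:
        e_in = sum(1 for u, v in edges if u in comm and v in comm)
        d_sum = sum(degree.get(n, 0) for n in comm)
        q += e_in / m - (d_sum / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def textbook_km(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate at each distinct observed time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(times)
    s = 1.0
    out = []
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        deaths = int(np.sum((times == t) & (events == 1)))
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        out.append(s)
    return uniq, np.array(out)


def textbook_logrank(times_a, events_a, times_b, events_b) -> float:
    """Unweighted log-rank chi-square from the O−E / hypergeometric-variance table."""
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    events_a = np.asarray(events_a, int)
    events_b = np.asarray(events_b, int)
    all_times = np.unique(np.concatenate([times_a[events_a == 1],
                                          times_b[events_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = int(np.sum(times_a >= t))
        n_b = int(np.sum(times_b >= t))
        d_a = int(np.sum((times_a == t) & (events_a == 1)))
        d_b = int(np.sum((times_b == t) & (events_b == 1)))
        n = n_a + n_b
        d = d_a + d_b
        if n < 2 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


# ---------------------------------------------------------------------------
# hypergeometric enumeration
# ---------------------------------------------------------------------------


def enumerate_hypergeom_tail(N: int, K_set: int, n_q: int, k: int) -> float:
    """P(X ≥ k) by counting draws of n_q from N containing ≥ k of the K_set."""
    total = comb(N, n_q)
    count = sum(
        comb(K_set, x) * comb(N - K_set, n_q - x)
        for x in range(k, min(K_set, n_q) + 1)
        if n_q - x <= N - K_set
    )
    return count / total
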