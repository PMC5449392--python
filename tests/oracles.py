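"""Independent brute-force oracles used to validate the implementation.

Everything here is computed from first principles (exhaustive path
enumeration, direct distance-matrix formulas, per-pair linear solves,
combinatorial enumeration) and deliberately shares no code with the package
internals beyond the graph container.
"""
from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def distance_matrix(g: nx.Graph, nodes):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist[idx[src], idx[dst]] = d
    return dist


def brute_betweenness_stress(g: nx.Graph, nodes):
    """Exhaustive all-shortest-paths enumeration over unordered pairs."""
    bet = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_shortest_paths(g, s, t))
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / sigma
            stress[v] += through
    return bet, stress


def brute_closeness(dist, i):
    n = dist.shape[0]
    return (n - 1) / dist[i].sum()


def brute_radiality(dist, i):
    n = dist.shape[0]
    diam = dist.max()
    return sum(diam + 1 - dist[i, j] for j in range(n) if j != i) / (n - 1)


def brute_centroid(dist, i):
    """min over u of gamma_i(u) - gamma_u(i), counting strictly closer nodes."""
    n = dist.shape[0]
    vals = []
    for u in range(n):
        if u == i:
            continue
        gamma_vu = sum(
            1 for w in range(n) if w not in (u, i) and dist[w, i] < dist[w, u]
        )
        gamma_uv = sum(
            1 for w in range(n) if w not in (u, i) and dist[w, u] < dist[w, i]
        )
        vals.append(gamma_vu - gamma_uv)
    return min(vals)


def brute_global_efficiency(g: nx.Graph):
    nodes = list(g.nodes())
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    lengths = dict(nx.all_pairs_shortest_path_length(g))
    for s in nodes:
        for t in nodes:
            if s != t and t in lengths[s]:
                total += 1.0 / lengths[s][t]
    return total / (n * (n - 1))


def brute_vulnerability(g: nx.Graph, v):
    base = brute_global_efficiency(g)
    h = g.copy()
    h.remove_node(v)
    return (base - brute_global_efficiency(h)) / base


def brute_pagerank(g: nx.Graph, nodes, damping=0.85, iters=10000):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    p = np.full(n, 1.0 / n)
    for _ in range(iters):
        nxt = np.full(n, (1.0 - damping) / n)
        for v in nodes:
            deg = g.degree(v)
            for u in g.neighbors(v):
                nxt[idx[u]] += damping * p[idx[v]] / deg
        if np.abs(nxt - p).sum() < 1e-14:
            p = nxt
            break
        p = nxt
    return p


def _pair_currents(g: nx.Graph, nodes, s, t):
    """Edge currents for a unit injection at s and extraction at t."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    lap = np.zeros((n, n))
    for u, v in g.edges():
        lap[idx[u], idx[u]] += 1
        lap[idx[v], idx[v]] += 1
        lap[idx[u], idx[v]] -= 1
        lap[idx[v], idx[u]] -= 1
    rhs = np.zeros(n)
    rhs[idx[s]] = 1.0
    rhs[idx[t]] = -1.0
    # ground one node to make the system solvable
    lap_g = lap.copy()
    lap_g[0, :] = 0.0
    lap_g[0, 0] = 1.0
    rhs_g = rhs.copy()
    rhs_g[0] = 0.0 if nodes[0] not in (s, t) else rhs_g[0]
    if nodes[0] in (s, t):
        # ground a different node
        k = next(i for i, v in enumerate(nodes) if v not in (s, t))
        lap_g = lap.copy()
        lap_g[k, :] = 0.0
        lap_g[k, k] = 1.0
        rhs_g = rhs.copy()
        rhs_g[k] = 0.0
    pot = np.linalg.solve(lap_g, rhs_g)
    return {(u, v): pot[idx[u]] - pot[idx[v]] for u, v in g.edges()}


def brute_current_flow_betweenness(g: nx.Graph, nodes):
    """Newman's random-walk betweenness: endpoint throughput counts as 1."""
    out = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        currents = _pair_currents(g, nodes, s, t)
        for v in nodes:
            if v in (s, t):
                out[v] += 1.0
            else:
                flow = sum(
                    abs(c) for (a, b), c in currents.items() if v in (a, b)
                )
                out[v] += flow / 2.0
    return out


def brute_current_flow_closeness(g: nx.Graph, nodes):
    """(n-1) / sum of pairwise effective resistances."""
    n = len(nodes)
    out = {}
    for v in nodes:
        total = sum(
            _effective_resistance(g, nodes, v, u) for u in nodes if u != v
        )
        out[v] = (n - 1) / total
    return out


def _effective_resistance(g: nx.Graph, nodes, s, t):
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    lap = np.zeros((n, n))
    for u, v in g.edges():
        lap[idx[u], idx[u]] += 1
        lap[idx[v], idx[v]] += 1
        lap[idx[u], idx[v]] -= 1
        lap[idx[v], idx[u]] -= 1
    pinv = np.linalg.pinv(lap)
    i, j = idx[s], idx[t]
    return pinv[i, i] + pinv[j, j] - 2 * pinv[i, j]


def brute_modularity_best_two_way(g: nx.Graph):
    """Exhaustive best modularity over all 2-set partitions."""
    nodes = list(g.nodes())
    best = -1.0
    for size in range(1, len(nodes)):
        for left in itertools.combinations(nodes, size):
            part = [set(left), set(nodes) - set(left)]
            q = nx.community.modularity(g, part)
            best = max(best, q)
    return best


def enumerate_hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """P(at least b successes) by enumerating all C(N, n) draws."""
    population = list(range(N))
    successes = set(range(B))
    hits = 0
    total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= b:
            hits += 1
    return hits / total


def random_connected_graph(rng: np.random.Generator, n_min=3, n_max=7) -> nx.Graph:
    """Seeded random connected simple graph with n_min..n_max nodes."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n >= 2 and nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
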