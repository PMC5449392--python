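"""Node centralities, rank tables, rank correlation and consensus ranking.

Eleven centrality measures are supported, with the exact per-node definitions
documented on each helper.  Genes are ranked per measure (rank 1 = highest
score); fractional (tie-averaged) ranks feed rank correlation, while ordinal
ranks (ties broken by ascending gene id) feed selection and the rank-sum
consensus.  Measures whose rankings are perfectly correlated are collapsed so
that only one representative enters the consensus.

The shortest-path machinery (path counts and dependency accumulation for
betweenness and stress) is a level-synchronous, all-sources-at-once
vectorization of Brandes' algorithm over the hop-distance matrix, which keeps
exact integer path counts while scaling to a few thousand nodes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csgraph
from scipy.sparse.linalg import eigsh

from .network import adjacency_and_distances, _efficiency_from_distances

#: Canonical measure order; redundancy pruning keeps the first member of each
#: perfectly-correlated group in this order.
CANONICAL_MEASURES = (
    "degree",
    "closeness",
    "radiality",
    "betweenness",
    "current_flow_betweenness",
    "current_flow_closeness",
    "centroid",
    "pagerank",
    "vulnerability",
    "stress",
    "eigenvector",
)

#: Measures computable from sparse BFS / spectral primitives alone; the
#: recommended set for large inputs (the remaining four require an all-pairs
#: node-removal sweep or dense Laplacian algebra that scales cubically).
FAST_MEASURES = (
    "degree",
    "closeness",
    "radiality",
    "betweenness",
    "stress",
    "pagerank",
    "eigenvector",
)

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-12


@dataclass
class CentralityTable:
    """Per-gene centrality scores with fractional and ordinal ranks."""

    measures: tuple[str, ...]
    scores: pd.DataFrame
    fractional_ranks: pd.DataFrame
    ordinal_ranks: pd.DataFrame


@dataclass
class ConsensusRanking:
    """Rank-sum consensus over a set of retained measures.

    ``rank_sum`` maps gene -> sum of ordinal ranks; ``consensus_rank`` maps
    gene -> ordinal position by ascending rank sum (ties broken by gene id);
    ``order`` lists genes best-first.
    """

    rank_sum: pd.Series
    consensus_rank: pd.Series
    order: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shortest-path counting machinery


def _sigma_matrix(adj, dist: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path counts sigma[s, t] (sigma[s, s] = 1)."""
    n = dist.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    diam = int(dist[np.isfinite(dist)].max())
    for d in range(1, diam + 1):
        frontier = sigma * (dist == d - 1)
        grown = frontier @ adj
        sigma += grown * (dist == d)
    return sigma


def _betweenness_stress(adj, dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact shortest-path betweenness and stress for every node.

    Betweenness counts each unordered (s, t) pair once with pair dependency
    sigma_st(v)/sigma_st; stress counts the number of shortest paths passing
    through v over unordered pairs.  Both use backward (deep-to-shallow)
    dependency accumulation, vectorized over all sources.
    """
    n = dist.shape[0]
    sigma = _sigma_matrix(adj, dist)
    diam = int(dist[np.isfinite(dist)].max())
    delta = np.zeros((n, n))  # Brandes dependency, per (source, node)
    tails = np.zeros((n, n))  # descending-path counts, per (source, node)
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    for d in range(diam, 0, -1):
        at_d = dist == d
        gb = ((1.0 + delta) / safe_sigma) * at_d
        gs = (1.0 + tails) * at_d
        prev = dist == d - 1
        delta += sigma * (gb @ adj) * prev
        tails += (gs @ adj) * prev
    np.fill_diagonal(delta, 0.0)
    paths_through = sigma * tails
    np.fill_diagonal(paths_through, 0.0)
    return delta.sum(axis=0) / 2.0, paths_through.sum(axis=0) / 2.0


# ---------------------------------------------------------------------------
# individual measures


def _closeness(dist: np.ndarray) -> np.ndarray:
    """(n-1) / sum of hop distances to all other nodes."""
    n = dist.shape[0]
    return (n - 1) / dist.sum(axis=1)


def _radiality(dist: np.ndarray) -> np.ndarray:
    """sum_u (diameter + 1 - d(v, u)) / (n - 1); monotone in total distance."""
    n = dist.shape[0]
    diam = dist.max()
    return ((diam + 1) * (n - 1) - dist.sum(axis=1)) / (n - 1)


def _centroid(dist: np.ndarray) -> np.ndarray:
    """centroid(v) = min_u (gamma_v(u) - gamma_u(v)).

    gamma_v(u) counts nodes w (w != u, v) strictly closer to v than to u.  The
    w = u and w = v correction terms cancel in the difference, so the value is
    the plain signed comparison sum over all w.
    """
    n = dist.shape[0]
    out = np.empty(n)
    for v in range(n):
        signed = np.sign(dist - dist[:, v][:, None]).sum(axis=0)
        signed[v] = np.inf  # exclude u = v from the minimum
        out[v] = signed.min()
    return out


def _eigenvector(adj, n: int) -> np.ndarray:
    """Principal adjacency eigenvector, L2-normalized and nonnegative."""
    if n <= 256:
        w, v = np.linalg.eigh(adj.toarray())
        vec = v[:, int(np.argmax(w))]
    else:
        _, v = eigsh(adj, k=1, which="LA", tol=0)
        vec = v[:, 0]
    if vec.sum() < 0:
        vec = -vec
    vec = np.abs(vec)  # Perron vector of a connected graph is strictly positive
    return vec / np.linalg.norm(vec)


def _pagerank(net: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    pr = nx.pagerank(net, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL, max_iter=1000)
    return np.array([pr[v] for v in nodes])


def _laplacian_pinv(adj) -> np.ndarray:
    dense = adj.toarray()
    lap = np.diag(dense.sum(axis=1)) - dense
    n = lap.shape[0]
    # pseudo-inverse via the rank-one shift trick (connected graph: nullspace
    # is the constant vector)
    j = np.full((n, n), 1.0 / n)
    return np.linalg.inv(lap + j) - j


def _current_flow_closeness(adj) -> np.ndarray:
    """Information centrality: (n-1) / sum of effective resistances."""
    pinv = _laplacian_pinv(adj)
    n = pinv.shape[0]
    diag = np.diag(pinv)
    reff_sum = n * diag + diag.sum() - 2.0 * pinv.sum(axis=1)
    return (n - 1) / reff_sum


def _current_flow_betweenness(adj) -> np.ndarray:
    """Newman's random-walk betweenness via the Laplacian pseudo-inverse.

    For each unordered source/sink pair a unit current is injected and the
    throughput of node v is half the sum of absolute currents on its incident
    edges; source and sink each count a throughput of 1.  The per-edge pair
    sums are evaluated with the sorted-potential trick; the spurious half-unit
    endpoint throughput picked up by the raw edge sums is corrected in closed
    form (the potential field is extremal at the endpoints, so each endpoint's
    raw contribution per pair is exactly 1/2).
    """
    pinv = _laplacian_pinv(adj)
    n = pinv.shape[0]
    rows, cols = adj.nonzero()
    raw = np.zeros(n)
    coeff = 2.0 * np.arange(n) - n + 1.0
    for i, j in zip(rows, cols):
        if i >= j:
            continue
        x = np.sort(pinv[i] - pinv[j])
        pair_sum = float(coeff @ x)  # sum over s < t of |x_s - x_t|
        raw[i] += 0.5 * pair_sum
        raw[j] += 0.5 * pair_sum
    return raw + (n - 1) / 2.0


def _vulnerability(adj, dist: np.ndarray) -> np.ndarray:
    """(E - E_v) / E, with E_v the global efficiency after deleting node v.

    E_v is computed on the remaining n-1 nodes, so removing a leaf typically
    *raises* efficiency and yields a negative vulnerability.
    """
    n = dist.shape[0]
    base = _efficiency_from_distances(dist)
    out = np.empty(n)
    idx = np.arange(n)
    for v in range(n):
        keep = idx != v
        sub = adj[keep][:, keep]
        sub_dist = csgraph.shortest_path(sub, method="D", unweighted=True)
        out[v] = (base - _efficiency_from_distances(sub_dist)) / base
    return out


def compute_centralities(
    net: nx.Graph, measures: Iterable[str] = CANONICAL_MEASURES
) -> CentralityTable:
    """Compute the requested centrality measures for a connected network.

    Raises if the graph is disconnected (closeness, radiality, current-flow
    and vulnerability are undefined there) or if a measure name is unknown.
    """
    measures = tuple(measures)
    unknown = [m for m in measures if m not in CANONICAL_MEASURES]
    if unknown:
        raise ValueError(f"unknown centrality measure(s): {unknown}")
    if net.number_of_nodes() < 2:
        raise ValueError("centrality analysis requires >= 2 nodes")
    if not nx.is_connected(net):
        raise ValueError(
            "network must be connected (closeness/radiality/current-flow/"
            "vulnerability are undefined on disconnected graphs)"
        )
    nodes = sorted(net.nodes())
    adj_sparse, dist = adjacency_and_distances(net, nodes)
    adj = adj_sparse  # csr; dense ops use .toarray() where needed
    n = len(nodes)

    cache: dict[str, np.ndarray] = {}

    def _bs():
        if "betweenness" not in cache:
            bet, stress = _betweenness_stress(adj, dist)
            cache["betweenness"], cache["stress"] = bet, stress
        return cache

    columns: dict[str, np.ndarray] = {}
    for m in measures:
        if m == "degree":
            columns[m] = np.asarray(adj.sum(axis=1)).ravel()
        elif m == "closeness":
            columns[m] = _closeness(dist)
        elif m == "radiality":
            columns[m] = _radiality(dist)
        elif m == "betweenness":
            columns[m] = _bs()["betweenness"]
        elif m == "stress":
            columns[m] = _bs()["stress"]
        elif m == "centroid":
            columns[m] = _centroid(dist)
        elif m == "eigenvector":
            columns[m] = _eigenvector(adj, n)
        elif m == "pagerank":
            columns[m] = _pagerank(net, nodes)
        elif m == "current_flow_closeness":
            columns[m] = _current_flow_closeness(adj)
        elif m == "current_flow_betweenness":
            columns[m] = _current_flow_betweenness(adj)
        elif m == "vulnerability":
            columns[m] = _vulnerability(adj, dist)
    scores = pd.DataFrame(columns, index=nodes).loc[:, list(measures)]
    fractional, ordinal = rank_table(scores)
    return CentralityTable(measures, scores, fractional, ordinal)


# ---------------------------------------------------------------------------
# ranking, correlation, consensus


def rank_table(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractional and ordinal rank tables (rank 1 = highest score).

    Fractional ranks average over score ties; ordinal ranks break ties by
    ascending gene id, giving a total order.
    """
    if scores.isna().any().any():
        raise ValueError("scores contain NaN")
    fractional = scores.rank(ascending=False, method="average")
    ids = scores.index.to_numpy(dtype=object)
    ordinal = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for col in scores.columns:
        vals = scores[col].to_numpy(dtype=float)
        order = np.lexsort((ids, -vals))  # score desc, then gene id asc
        ranks = np.empty(len(ids))
        ranks[order] = np.arange(1, len(ids) + 1)
        ordinal[col] = ranks
    return fractional, ordinal


def spearman_rho(ranks_a: Mapping[str, float] | pd.Series, ranks_b) -> float:
    """Spearman rank correlation of two rankings over the same gene set.

    Computed as the product-moment correlation of the (fractional) rank
    vectors, which reduces to 1 - 6*sum(d_i^2)/(n*(n^2-1)) when tie-free.
    """
    a = pd.Series(ranks_a)
    b = pd.Series(ranks_b)
    if set(a.index) != set(b.index):
        raise ValueError("rankings must cover the same gene set")
    b = b.loc[a.index]
    if len(a) < 2:
        raise ValueError("need at least two genes")
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("rank correlation undefined for a constant ranking")
    return float(np.corrcoef(av, bv)[0, 1])


def rank_correlation_matrix(fractional_ranks: pd.DataFrame) -> pd.DataFrame:
    """Measure-by-measure Spearman matrix from a fractional rank table."""
    cols = list(fractional_ranks.columns)
    mat = np.corrcoef(fractional_ranks.to_numpy(dtype=float), rowvar=False)
    mat = np.atleast_2d(mat)
    return pd.DataFrame(mat, index=cols, columns=cols)


def prune_redundant_measures(
    rho: pd.DataFrame, threshold: float = 1.0, atol: float = 1e-9
) -> list[str]:
    """Collapse groups of measures pairwise rank-correlated at >= threshold.

    Grouping is transitive; from each group only the first measure in the
    matrix's column order (the canonical order) is retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cols = list(rho.columns)
    parent = {c: c for c in cols}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if rho.loc[a, b] >= threshold - atol:
                parent[find(b)] = find(a)
    kept: list[str] = []
    seen: set[str] = set()
    for c in cols:
        root = find(c)
        if root not in seen:
            seen.add(root)
            kept.append(c)
    return kept


def consensus_ranking(ordinal_ranks: pd.DataFrame) -> ConsensusRanking:
    """Sum ordinal ranks over the retained measures and rank by the sum.

    Lower rank sum = more central overall; ties are broken by gene id.
    """
    if ordinal_ranks.shape[1] < 1:
        raise ValueError("need at least one retained measure")
    rank_sum = ordinal_ranks.sum(axis=1)
    order = sorted(rank_sum.index, key=lambda g: (rank_sum[g], g))
    consensus = pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order), dtype=float
    ).loc[rank_sum.index]
    return ConsensusRanking(rank_sum=rank_sum, consensus_rank=consensus, order=order)


def select_top_fraction(
    ranking: ConsensusRanking | pd.Series | Mapping[str, float],
    fraction: float,
    policy: str = "round",
    scores: pd.Series | None = None,
) -> list[str]:
    """Return the top ``fraction`` of genes in ordinal rank order.

    ``policy`` controls the list size k for n genes: ``round`` (half-up
    rounding of fraction*n, the default), ``floor``, or ``distinct`` which
    extends the rounded cut to include every gene tying the boundary score
    (requires ``scores``).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if isinstance(ranking, ConsensusRanking):
        order = list(ranking.order)
    else:
        series = pd.Series(ranking)
        order = sorted(series.index, key=lambda g: (series[g], g))
    n = len(order)
    if policy == "round":
        k = int(np.floor(fraction * n + 0.5))
    elif policy == "floor":
        k = int(np.floor(fraction * n))
    elif policy == "distinct":
        if scores is None:
            raise ValueError("policy 'distinct' requires a score series")
        k = int(np.floor(fraction * n + 0.5))
        if k >= 1:
            boundary = scores[order[k - 1]]
            while k < n and scores[order[k]] == boundary:
                k += 1
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    if k < 1:
        raise ValueError(f"fraction {fraction} selects zero genes from n={n}")
    return order[:k]
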