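"""Scored interaction networks: parsing, construction and topology.

The analysis operates on an undirected, unweighted gene network obtained by
confidence-filtering a scored protein-protein interaction list, restricting it
to a universe of candidate genes, and keeping the largest connected component.
Edge confidence scores are used only for filtering; all distances are hop
counts.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

DIALECTS = ("simple3col", "hippie")


@dataclass(frozen=True)
class ScoredInteraction:
    """One scored undirected interaction between two genes."""

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("gene identifiers must be non-empty strings")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"confidence score {self.score!r} outside [0, 1]")


@dataclass(frozen=True)
class TopologySummary:
    """Whole-network topology metrics of a connected network.

    ``powerlaw_exponent`` is the gamma of P(K) ~ K**-gamma fitted to the degree
    distribution; it is NaN when the distribution has fewer than three support
    points.
    """

    average_degree: float
    diameter: float
    average_distance: float
    density: float
    modularity: float
    global_efficiency: float
    average_clustering: float
    powerlaw_exponent: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _iter_data_lines(path):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_interactions(path, dialect: str = "simple3col") -> list[ScoredInteraction]:
    """Read a scored edge list in TSV form.

    ``simple3col`` rows are ``idA<TAB>idB<TAB>score``; ``hippie`` rows are
    ``idA<TAB>entrezA<TAB>idB<TAB>entrezB<TAB>score<TAB>evidence`` and the
    identifiers are taken from the Entrez columns.  Rows whose score cannot be
    parsed (or lies outside [0, 1]) are skipped with a warning.  Comment lines
    starting with ``#`` are ignored.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    out: list[ScoredInteraction] = []
    for lineno, line in _iter_data_lines(path):
        cols = line.split("\t")
        try:
            if dialect == "simple3col":
                if len(cols) < 3:
                    raise ValueError("need >= 3 columns")
                a, b, score_str = cols[0], cols[1], cols[2]
            else:
                if len(cols) < 5:
                    raise ValueError("need >= 5 columns")
                a, b, score_str = cols[1], cols[3], cols[4]
            out.append(ScoredInteraction(a.strip(), b.strip(), float(score_str)))
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: skipping row (%s)", path, lineno, exc)
    if not out:
        raise ValueError(f"no parseable interactions in {path}")
    return out


def read_scored_genes(path, cutoff: float) -> set[str]:
    """Read a two-column (gene, score) TSV and keep genes with score >= cutoff."""
    kept: set[str] = set()
    any_row = False
    for lineno, line in _iter_data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            logger.warning("%s:%d: skipping row (need 2 columns)", path, lineno)
            continue
        try:
            score = float(cols[1])
        except ValueError as exc:
            logger.warning("%s:%d: skipping row (%s)", path, lineno, exc)
            continue
        any_row = True
        if score >= cutoff:
            kept.add(cols[0].strip())
    if not any_row:
        raise ValueError(f"no parseable gene rows in {path}")
    if not kept:
        raise ValueError(f"no genes pass score cutoff {cutoff}")
    return kept


def build_network(
    interactions: Iterable[ScoredInteraction],
    universe: set[str],
    score_cutoff: float = 0.63,
) -> nx.Graph:
    """Build the filtered largest-component network.

    Edges are retained iff their score is >= ``score_cutoff`` and both
    endpoints belong to ``universe``.  Self-loops are dropped, parallel edges
    are collapsed keeping the maximum score, and the largest connected
    component of the surviving graph is returned (ties between equally sized
    components are broken in favour of the one containing the
    lexicographically smallest gene id).
    """
    if not 0.0 <= score_cutoff <= 1.0:
        raise ValueError("score_cutoff must lie in [0, 1]")
    if not universe:
        raise ValueError("gene universe is empty")
    graph = nx.Graph()
    for it in interactions:
        if it.score < score_cutoff or it.gene_a == it.gene_b:
            continue
        if it.gene_a not in universe or it.gene_b not in universe:
            continue
        if graph.has_edge(it.gene_a, it.gene_b):
            graph[it.gene_a][it.gene_b]["score"] = max(
                graph[it.gene_a][it.gene_b]["score"], it.score
            )
        else:
            graph.add_edge(it.gene_a, it.gene_b, score=it.score)
    if graph.number_of_edges() == 0:
        raise ValueError("no interactions survive the filters")
    components = list(nx.connected_components(graph))
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    best = min(tied, key=min)
    return graph.subgraph(best).copy()


def adjacency_and_distances(net: nx.Graph, nodelist: Sequence[str]):
    """CSR adjacency and the all-pairs hop-distance matrix for ``nodelist``."""
    adj = nx.to_scipy_sparse_array(net, nodelist=nodelist, dtype=float, format="csr")
    dist = csgraph.shortest_path(adj, method="D", unweighted=True)
    return adj, dist


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def degree_distribution(net: nx.Graph) -> dict[int, float]:
    """Map degree K -> fraction of nodes with that degree (P(K))."""
    n = net.number_of_nodes()
    counts: dict[int, int] = {}
    for _, deg in net.degree():
        counts[deg] = counts.get(deg, 0) + 1
    return {k: c / n for k, c in sorted(counts.items())}


def fit_power_law(degree_histogram: Mapping[int, float]) -> float:
    """Fit P(K) ~ K**-gamma by ordinary least squares on log K vs log P(K).

    Degrees with zero (or negative) frequency, and degree zero itself, are
    excluded.  Requires at least three support points.
    """
    ks = np.array([k for k, p in degree_histogram.items() if k > 0 and p > 0], dtype=float)
    ps = np.array([p for k, p in degree_histogram.items() if k > 0 and p > 0], dtype=float)
    if ks.size < 3:
        raise ValueError("power-law fit needs >= 3 degrees with positive frequency")
    slope, _ = np.polyfit(np.log(ks), np.log(ps), 1)
    return float(-slope)


def summarize_topology(
    net: nx.Graph, seed: int = 0, community_algorithm: str = "louvain"
) -> TopologySummary:
    """Compute whole-network topology metrics for a connected network.

    Modularity is that of a greedy modularity-maximizing partition; the
    algorithm is pluggable (``louvain`` uses the given seed, ``greedy`` is the
    deterministic agglomerative CNM variant).  The reported value is partition-
    and algorithm-dependent.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("topology summary requires >= 2 nodes")
    if not nx.is_connected(net):
        raise ValueError("network must be connected")
    nodes = sorted(net.nodes())
    _, dist = adjacency_and_distances(net, nodes)
    m = net.number_of_edges()
    off = dist[~np.eye(n, dtype=bool)]
    if community_algorithm == "louvain":
        communities = nx.community.louvain_communities(net, seed=seed)
    elif community_algorithm == "greedy":
        communities = nx.community.greedy_modularity_communities(net)
    else:
        raise ValueError(f"unknown community algorithm {community_algorithm!r}")
    modularity = nx.community.modularity(net, communities)
    try:
        gamma = fit_power_law(degree_distribution(net))
    except ValueError:
        gamma = math.nan
    return TopologySummary(
        average_degree=2.0 * m / n,
        diameter=float(off.max()),
        average_distance=float(off.mean()),
        density=2.0 * m / (n * (n - 1)),
        modularity=float(modularity),
        global_efficiency=_efficiency_from_distances(dist),
        average_clustering=float(nx.average_clustering(net)),
        powerlaw_exponent=gamma,
    )


def write_network(net: nx.Graph, path, header: str | None = None) -> None:
    """Write a network as a simple3col TSV (idA, idB, score)."""
    with open(path, "w") as handle:
        if header:
            for line in header.splitlines():
                handle.write(f"# {line}\n")
        for a, b, data in sorted(net.edges(data=True)):
            handle.write(f"{a}\t{b}\t{data.get('score', 1.0):g}\n")


def read_network(path) -> nx.Graph:
    """Read a simple3col TSV back into a graph (no filtering applied)."""
    graph = nx.Graph()
    for it in read_interactions(path, dialect="simple3col"):
        graph.add_edge(it.gene_a, it.gene_b, score=it.score)
    return graph
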