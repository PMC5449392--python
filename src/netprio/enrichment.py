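"""Ontology handling, over-representation analysis and term pruning.

Implements two-list hypergeometric enrichment of a target gene set against a
background, the three term-selection criteria used downstream (term-size
filtering, top-fraction selection, semantic-redundancy pruning), information
content and Resnik/Lin similarity over an is_a DAG, expansion of surviving
terms back to genes, and generic GMT gene-set over-representation.

The statistic throughout is the plain hypergeometric upper tail; thresholds
are applied to raw p-values (no multiple-testing correction), and the three
ontology namespaces are processed independently since they form disjoint
DAGs.  The information-content reference corpus is the loaded annotation set
itself, with natural-log IC.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


@dataclass(frozen=True)
class TermInfo:
    name: str
    namespace: str  # one of BP / MF / CC
    parents: tuple[str, ...]


class OntologyDag:
    """A GO-like term DAG restricted to is_a relations."""

    def __init__(self, terms: Mapping[str, TermInfo]):
        self.terms = dict(terms)
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term, info in self.terms.items():
            for parent in info.parents:
                if parent not in self.terms:
                    raise ValueError(f"term {term} has unknown parent {parent}")
                graph.add_edge(term, parent)
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology contains an is_a cycle")

    def namespace(self, term: str) -> str:
        return self.terms[term].namespace

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable via is_a edges (ancestor closure)."""
        if term not in self._ancestor_cache:
            acc: set[str] = {term}
            stack = list(self.terms[term].parents)
            while stack:
                t = stack.pop()
                if t not in acc:
                    acc.add(t)
                    stack.extend(self.terms[t].parents)
            self._ancestor_cache[term] = frozenset(acc)
        closure = self._ancestor_cache[term]
        return closure if include_self else closure - {term}

    def roots(self, namespace: str | None = None) -> frozenset[str]:
        return frozenset(
            t
            for t, info in self.terms.items()
            if not info.parents and (namespace is None or info.namespace == namespace)
        )


@dataclass
class AnnotationMap:
    """Gene-term annotations with ancestor closure and term information content."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    term_genes: dict[str, frozenset[str]]  # propagated, term -> genes
    ic: dict[str, float]
    dag: OntologyDag


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    namespace: str
    b: int  # target genes annotated to the term
    n: int  # target size
    B: int  # background genes annotated to the term
    N: int  # background size
    enrichment: float  # (b/n) / (B/N)
    p: float  # hypergeometric upper tail


@dataclass(frozen=True)
class GeneSetResult:
    name: str
    b: int
    n: int
    B: int
    N: int
    expected: float
    enrichment: float
    p: float


# ---------------------------------------------------------------------------
# ontology + annotation input


def read_obo(path) -> OntologyDag:
    """Read an OBO 1.2 file (id, name, namespace, is_a) into an OntologyDag."""
    graph = obonet.read_obo(path)
    terms: dict[str, TermInfo] = {}
    for term, data in graph.nodes(data=True):
        ns = NAMESPACE_CODES.get(data.get("namespace", ""), None)
        if ns is None:
            raise ValueError(f"term {term} has missing/unknown namespace")
        parents = tuple(sorted(data.get("is_a", [])))
        terms[term] = TermInfo(name=data.get("name", term), namespace=ns, parents=parents)
    return OntologyDag(terms)


def build_annotation_map(
    direct: Mapping[str, Iterable[str]], dag: OntologyDag
) -> AnnotationMap:
    """Propagate direct annotations to ancestors and compute term IC.

    IC(term) = -ln(genes annotated to term / genes annotated in the term's
    namespace), using the loaded corpus as the reference; the namespace corpus
    size is the number of genes carrying at least one annotation there.
    """
    direct_sets = {g: frozenset(ts) for g, ts in direct.items() if ts}
    propagated: dict[str, frozenset[str]] = {}
    term_genes: dict[str, set[str]] = {}
    for gene, ts in direct_sets.items():
        closure: set[str] = set()
        for t in ts:
            closure |= dag.ancestors(t)
        propagated[gene] = frozenset(closure)
        for t in closure:
            term_genes.setdefault(t, set()).add(gene)
    ns_corpus: dict[str, int] = {}
    for ns in ("BP", "MF", "CC"):
        genes_ns = {
            g
            for g, ts in propagated.items()
            if any(dag.namespace(t) == ns for t in ts)
        }
        ns_corpus[ns] = len(genes_ns)
    ic: dict[str, float] = {}
    for term, genes in term_genes.items():
        corpus = ns_corpus[dag.namespace(term)]
        ic[term] = -math.log(len(genes) / corpus) if corpus else math.inf
    return AnnotationMap(
        direct=direct_sets,
        propagated=propagated,
        term_genes={t: frozenset(g) for t, g in term_genes.items()},
        ic=ic,
        dag=dag,
    )


def read_annotations(path, dag: OntologyDag) -> AnnotationMap:
    """Read a gene<TAB>term TSV; annotations to unknown terms are skipped."""
    direct: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                logger.warning("%s:%d: skipping row (need 2 columns)", path, lineno)
                continue
            gene, term = cols[0].strip(), cols[1].strip()
            if term not in dag.terms:
                logger.warning("%s:%d: unknown term %s, skipped", path, lineno, term)
                continue
            direct.setdefault(gene, set()).add(term)
    return build_annotation_map(direct, dag)


# ---------------------------------------------------------------------------
# enrichment


def hypergeom_upper_tail(b: int, N: int, B: int, n: int) -> float:
    """P(X >= b) for X ~ Hypergeom(N population, B successes, n draws)."""
    return float(hypergeom.sf(b - 1, N, B, n))


def _result_sort_key(r: EnrichmentResult):
    return (r.p, -r.enrichment, r.term)


def enrich_two_list(
    target: set[str],
    background: set[str],
    ann: AnnotationMap,
    p_threshold: float = 0.001,
) -> list[EnrichmentResult]:
    """Two-list over-representation of ontology terms in target vs background.

    For every term annotating at least one target gene, the hypergeometric
    upper-tail probability of drawing b or more annotated genes in n draws
    from a background of N genes of which B are annotated.  Terms with
    p < ``p_threshold`` are returned sorted by ascending p (ties: descending
    enrichment, then term id).
    """
    target, background = set(target), set(background)
    if not target <= background:
        raise ValueError("target gene set must be a subset of the background")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    N, n = len(background), len(target)
    out: list[EnrichmentResult] = []
    for term, genes in ann.term_genes.items():
        B = len(genes & background)
        b = len(genes & target)
        if b < 1 or B < 1:
            continue
        p = hypergeom_upper_tail(b, N, B, n)
        if p < p_threshold:
            out.append(
                EnrichmentResult(
                    term=term,
                    namespace=ann.dag.namespace(term),
                    b=b,
                    n=n,
                    B=B,
                    N=N,
                    enrichment=(b / n) / (B / N),
                    p=p,
                )
            )
    return sorted(out, key=_result_sort_key)


def filter_by_term_size(
    results: Sequence[EnrichmentResult], min_B: int = 3, max_B: int = 50
) -> list[EnrichmentResult]:
    """Keep terms whose background annotation count B satisfies min_B <= B <= max_B."""
    if min_B > max_B:
        raise ValueError("min_B must not exceed max_B")
    return [r for r in results if min_B <= r.B <= max_B]


def select_top_terms(
    results: Sequence[EnrichmentResult],
    fraction: float = 0.20,
    per_namespace: bool = True,
) -> list[EnrichmentResult]:
    """Keep the first floor(fraction * count) terms by ascending p.

    With ``per_namespace`` (default) the fraction is applied within each
    namespace separately.  Raises if the selection is empty.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    groups: dict[str, list[EnrichmentResult]] = {}
    if per_namespace:
        for r in results:
            groups.setdefault(r.namespace, []).append(r)
    else:
        groups["all"] = list(results)
    kept: list[EnrichmentResult] = []
    for rs in groups.values():
        rs = sorted(rs, key=_result_sort_key)
        kept.extend(rs[: int(math.floor(fraction * len(rs)))])
    if not kept:
        raise ValueError("top-fraction selection is empty")
    return sorted(kept, key=_result_sort_key)


# ---------------------------------------------------------------------------
# semantic similarity + pruning


def semantic_similarity(
    t1: str,
    t2: str,
    dag: OntologyDag,
    ic: Mapping[str, float],
    method: str = "lin",
) -> float:
    """Resnik or Lin similarity from the most informative common ancestor.

    resnik = IC(MICA); lin = 2*IC(MICA) / (IC(t1) + IC(t2)), defined as 0 when
    both term ICs are 0.  Terms must share a namespace.
    """
    if dag.namespace(t1) != dag.namespace(t2):
        raise ValueError("semantic similarity requires terms in the same namespace")
    common = dag.ancestors(t1) & dag.ancestors(t2)
    mica_ic = max((ic.get(t, 0.0) for t in common), default=0.0)
    if method == "resnik":
        return mica_ic
    if method == "lin":
        denom = ic.get(t1, 0.0) + ic.get(t2, 0.0)
        return 2.0 * mica_ic / denom if denom > 0 else 0.0
    raise ValueError(f"unknown similarity method {method!r}")


def prune_redundant_terms(
    results: Sequence[EnrichmentResult],
    dag: OntologyDag,
    ic: Mapping[str, float],
    sim_threshold: float = 0.7,
    method: str = "lin",
) -> list[EnrichmentResult]:
    """Greedy within-namespace removal of semantically redundant terms.

    Repeatedly find the most similar retained pair with similarity strictly
    above ``sim_threshold`` and discard the member with the larger p (ties:
    discard the smaller-IC, i.e. more general, term; then the larger term id);
    stop when no pair exceeds the threshold.
    """
    by_ns: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_ns.setdefault(r.namespace, []).append(r)
    survivors: list[EnrichmentResult] = []
    for rs in by_ns.values():
        retained = sorted(rs, key=_result_sort_key)
        sim_cache: dict[tuple[str, str], float] = {}

        def sim(a: EnrichmentResult, b: EnrichmentResult) -> float:
            key = (a.term, b.term) if a.term < b.term else (b.term, a.term)
            if key not in sim_cache:
                sim_cache[key] = semantic_similarity(a.term, b.term, dag, ic, method)
            return sim_cache[key]

        while len(retained) > 1:
            best: tuple[float, str, str] | None = None
            best_pair: tuple[int, int] | None = None
            for i in range(len(retained)):
                for j in range(i + 1, len(retained)):
                    s = sim(retained[i], retained[j])
                    ids = tuple(sorted((retained[i].term, retained[j].term)))
                    cand = (-s, *ids)
                    if best is None or cand < best:
                        best, best_pair = cand, (i, j)
            assert best is not None and best_pair is not None
            if -best[0] <= sim_threshold:
                break
            a, b = retained[best_pair[0]], retained[best_pair[1]]
            drop = _redundant_loser(a, b, ic)
            retained = [r for r in retained if r.term != drop.term]
        survivors.extend(retained)
    return sorted(survivors, key=_result_sort_key)


def _redundant_loser(
    a: EnrichmentResult, b: EnrichmentResult, ic: Mapping[str, float]
) -> EnrichmentResult:
    if a.p != b.p:
        return a if a.p > b.p else b
    ic_a, ic_b = ic.get(a.term, 0.0), ic.get(b.term, 0.0)
    if ic_a != ic_b:
        return a if ic_a < ic_b else b  # discard the more general term
    return a if a.term > b.term else b


def terms_to_genes(
    results: Sequence[EnrichmentResult], ann: AnnotationMap, net: nx.Graph
) -> set[str]:
    """Union of the surviving terms' annotated genes, restricted to the network."""
    nodes = set(net.nodes())
    genes: set[str] = set()
    for r in results:
        genes |= ann.term_genes.get(r.term, frozenset()) & nodes
    if not genes:
        raise ValueError("no network genes correspond to the surviving terms")
    return genes


# ---------------------------------------------------------------------------
# generic gene-set (GMT) over-representation


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read a GMT file: set name, description, then member genes."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for raw in handle:
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 3 or not cols[0].strip():
                continue
            sets[cols[0].strip()] = frozenset(g.strip() for g in cols[2:] if g.strip())
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def geneset_overrepresentation(
    genes: set[str],
    collections: Mapping[str, Iterable[str]],
    universe: set[str],
    p_threshold: float = 0.01,
) -> list[GeneSetResult]:
    """Expected-value over-representation of named gene sets in a query list.

    A set is reported when its observed overlap b exceeds the expected count
    n*B/N and the hypergeometric upper-tail p is below ``p_threshold``.
    """
    genes, universe = set(genes), set(universe)
    if not universe:
        raise ValueError("universe is empty")
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(genes)
    out: list[GeneSetResult] = []
    for name, members in collections.items():
        members = set(members) & universe
        B = len(members)
        b = len(members & genes)
        if b < 1 or B < 1:
            continue
        expected = n * B / N
        p = hypergeom_upper_tail(b, N, B, n)
        if p < p_threshold and b > expected:
            out.append(
                GeneSetResult(
                    name=name,
                    b=b,
                    n=n,
                    B=B,
                    N=N,
                    expected=expected,
                    enrichment=(b / n) / (B / N),
                    p=p,
                )
            )
    return sorted(out, key=lambda r: (r.p, -r.enrichment, r.name))
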