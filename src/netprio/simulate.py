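"""Synthetic data generator for the full prioritization pipeline.

Emulates the statistical regime the analysis assumes, so every stage runs and
is testable without external downloads:

* a scale-free interaction network (preferential attachment) with Beta-
  distributed edge confidence scores, plus decoy genes below the candidate
  score cutoff;
* a known disease-gene set sampled with probability proportional to
  degree**hub_bias (disease genes biased toward hubs);
* a three-namespace term DAG with planted enriched terms whose annotations
  are drawn preferentially from the disease genes;
* per-gene disease-association counts decaying log-linearly with rank
  percentile.

Every output is a pure function of the configuration, including its seed.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .centrality import ConsensusRanking
from .enrichment import OntologyDag, TermInfo
from .network import ScoredInteraction

_NS_FULL = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; the defaults are the benchmark conditions."""

    n_genes: int = 2000
    attachment_edges: int = 3
    n_disease_genes: int = 150
    hub_bias: float = 2.0
    score_alpha: float = 5.5
    score_beta: float = 2.0
    n_decoy_genes: int = 500
    n_terms: int = 300
    dag_depth: int = 4
    n_enriched_terms: int = 30
    enrichment_strength: float = 0.9
    term_size_range: tuple[int, int] = (10, 40)
    disease_count_rate: float = 5.0
    rank_effect: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.attachment_edges < 1 or self.n_genes <= self.attachment_edges:
            raise ValueError("need n_genes > attachment_edges >= 1")
        if not 0 < self.n_disease_genes < self.n_genes:
            raise ValueError("need 0 < n_disease_genes < n_genes")
        if self.hub_bias < 0:
            raise ValueError("hub_bias must be >= 0")
        if self.score_alpha <= 0 or self.score_beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.n_enriched_terms > self.n_terms:
            raise ValueError("n_enriched_terms cannot exceed n_terms")
        if not 0.0 <= self.enrichment_strength <= 1.0:
            raise ValueError("enrichment_strength must lie in [0, 1]")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid term_size_range")
        if self.rank_effect < 0 or self.disease_count_rate < 0:
            raise ValueError("rate parameters must be >= 0")
        if math.ceil(self.enrichment_strength * hi) > self.n_disease_genes:
            raise ValueError("disease set too small for the requested enrichment")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    interactions: list[ScoredInteraction]
    gene_scores: dict[str, float]  # candidate-gene scores (decoys below cutoff)
    disease_genes: frozenset[str]
    dag: OntologyDag
    annotations: dict[str, frozenset[str]]  # direct gene -> terms
    enriched_terms: frozenset[str]  # planted truth


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # independent stream per stage, all derived from the one seed
    return np.random.default_rng([cfg.seed, stage])


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def simulate_network(
    cfg: SyntheticConfig,
) -> tuple[list[ScoredInteraction], dict[str, float]]:
    """Preferential-attachment network with Beta confidence scores.

    Returns the scored edge list and a candidate-gene score map covering the
    network genes (scores >= 1) plus decoy genes (scores in [0.25, 1)) that a
    candidate cutoff of 1.0 removes.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    graph = nx.barabasi_albert_graph(
        cfg.n_genes, cfg.attachment_edges, seed=int(rng.integers(2**31))
    )
    edges = sorted((min(u, v), max(u, v)) for u, v in graph.edges())
    scores = rng.beta(cfg.score_alpha, cfg.score_beta, size=len(edges))
    interactions = [
        ScoredInteraction(_gene_id(u), _gene_id(v), float(s))
        for (u, v), s in zip(edges, scores)
    ]
    gene_scores = {
        _gene_id(i): float(x)
        for i, x in enumerate(rng.uniform(1.0, 2.0, size=cfg.n_genes))
    }
    for i, x in enumerate(rng.uniform(0.25, 0.999, size=cfg.n_decoy_genes)):
        gene_scores[f"D{i:05d}"] = float(x)
    return interactions, gene_scores


def plant_disease_genes(net: nx.Graph, cfg: SyntheticConfig) -> frozenset[str]:
    """Sample known disease genes without replacement, weight ~ degree**hub_bias."""
    cfg.validate()
    rng = _rng(cfg, 1)
    nodes = sorted(net.nodes())
    if cfg.n_disease_genes >= len(nodes):
        raise ValueError("n_disease_genes must be smaller than the network")
    deg = np.array([net.degree(v) for v in nodes], dtype=float)
    weights = deg**cfg.hub_bias
    weights /= weights.sum()
    chosen = rng.choice(len(nodes), size=cfg.n_disease_genes, replace=False, p=weights)
    return frozenset(nodes[i] for i in chosen)


def simulate_ontology_and_annotations(
    genes: Sequence[str],
    disease_genes: frozenset[str],
    cfg: SyntheticConfig,
) -> tuple[OntologyDag, dict[str, frozenset[str]], frozenset[str]]:
    """Random rooted DAG per namespace with planted enriched terms.

    Terms are spread over the three namespaces (80/10/10).  Every non-root
    term annotates a gene count drawn from ``term_size_range``; planted terms
    draw ceil(enrichment_strength * size) of their genes from the disease set
    and the rest uniformly from the remaining genes; other terms draw
    uniformly.  Returns the DAG, direct annotations and the planted term ids.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    genes = sorted(genes)
    disease = sorted(set(disease_genes) & set(genes))
    lo, hi = cfg.term_size_range
    if math.ceil(cfg.enrichment_strength * hi) > len(disease):
        raise ValueError("disease set too small for the requested enrichment")
    ns_counts = {"BP": max(2, int(round(cfg.n_terms * 0.8)))}
    ns_counts["MF"] = max(2, int(round(cfg.n_terms * 0.1)))
    ns_counts["CC"] = max(2, cfg.n_terms - ns_counts["BP"] - ns_counts["MF"])
    terms: dict[str, TermInfo] = {}
    non_root: list[str] = []
    counter = 0
    for ns in ("BP", "MF", "CC"):
        count = ns_counts[ns]
        counter += 1
        root = f"SYN:{counter:07d}"
        terms[root] = TermInfo(name=f"{ns} root", namespace=ns, parents=())
        levels: list[list[str]] = [[root]]
        depth = max(1, cfg.dag_depth)
        remaining = count - 1
        per_level = [remaining // depth + (1 if i < remaining % depth else 0) for i in range(depth)]
        for level_size in per_level:
            level: list[str] = []
            for _ in range(level_size):
                counter += 1
                tid = f"SYN:{counter:07d}"
                n_par = int(rng.integers(1, min(2, len(levels[-1])) + 1))
                parents = tuple(
                    sorted(rng.choice(levels[-1], size=n_par, replace=False).tolist())
                )
                terms[tid] = TermInfo(name=f"{ns} term {tid}", namespace=ns, parents=parents)
                level.append(tid)
                non_root.append(tid)
            if level:
                levels.append(level)
    dag = OntologyDag(terms)
    planted = rng.choice(non_root, size=cfg.n_enriched_terms, replace=False)
    planted_set = frozenset(str(t) for t in planted)
    gene_arr = np.array(genes, dtype=object)
    disease_arr = np.array(disease, dtype=object)
    other_arr = np.array([g for g in genes if g not in set(disease)], dtype=object)
    direct: dict[str, set[str]] = {}
    for tid in non_root:
        size = int(rng.integers(lo, hi + 1))
        if tid in planted_set:
            k = math.ceil(cfg.enrichment_strength * size)
            members = list(rng.choice(disease_arr, size=k, replace=False))
            if size - k > 0:
                members += list(rng.choice(other_arr, size=size - k, replace=False))
        else:
            members = list(rng.choice(gene_arr, size=min(size, len(gene_arr)), replace=False))
        for g in members:
            direct.setdefault(str(g), set()).add(tid)
    return dag, {g: frozenset(ts) for g, ts in direct.items()}, planted_set


def simulate_disease_counts(
    consensus: ConsensusRanking, cfg: SyntheticConfig
) -> dict[str, int]:
    """Poisson disease counts with log-linear decay in rank percentile.

    count(g) ~ Poisson(rate * exp(-rank_effect * percentile(g))) with the
    percentile 0 for the best-ranked gene and 1 for the worst; rank_effect 0
    gives the rank-independent null.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    order = list(consensus.order)
    n = len(order)
    pct = np.arange(n) / max(n - 1, 1)
    lam = cfg.disease_count_rate * np.exp(-cfg.rank_effect * pct)
    counts = rng.poisson(lam)
    return {g: int(c) for g, c in zip(order, counts)}


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate network, disease genes, ontology and annotations in one call."""
    interactions, gene_scores = simulate_network(cfg)
    graph = nx.Graph()
    for it in interactions:
        graph.add_edge(it.gene_a, it.gene_b, score=it.score)
    disease = plant_disease_genes(graph, cfg)
    dag, annotations, planted = simulate_ontology_and_annotations(
        sorted(graph.nodes()), disease, cfg
    )
    return SyntheticDataset(
        config=cfg,
        interactions=interactions,
        gene_scores=gene_scores,
        disease_genes=disease,
        dag=dag,
        annotations=annotations,
        enriched_terms=planted,
    )


# ---------------------------------------------------------------------------
# writers


def write_obo(dag: OntologyDag, path) -> None:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\n")
        for tid in sorted(dag.terms):
            info = dag.terms[tid]
            handle.write("\n[Term]\n")
            handle.write(f"id: {tid}\n")
            handle.write(f"name: {info.name}\n")
            handle.write(f"namespace: {_NS_FULL[info.namespace]}\n")
            for parent in info.parents:
                handle.write(f"is_a: {parent} ! {dag.terms[parent].name}\n")


def write_dataset(ds: SyntheticDataset, out_dir, header: str | None = None) -> dict[str, Path]:
    """Write all generated inputs as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "genes": out / "genes.tsv",
        "known": out / "known.txt",
        "obo": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.json",
    }
    prefix = "".join(f"# {line}\n" for line in (header or "").splitlines())
    with open(paths["edges"], "w") as handle:
        handle.write(prefix)
        for it in ds.interactions:
            handle.write(f"{it.gene_a}\t{it.gene_b}\t{it.score:.6f}\n")
    with open(paths["genes"], "w") as handle:
        handle.write(prefix)
        for gene in sorted(ds.gene_scores):
            handle.write(f"{gene}\t{ds.gene_scores[gene]:.6f}\n")
    with open(paths["known"], "w") as handle:
        handle.write(prefix)
        for gene in sorted(ds.disease_genes):
            handle.write(f"{gene}\n")
    write_obo(ds.dag, paths["obo"])
    with open(paths["annotations"], "w") as handle:
        handle.write(prefix)
        for gene in sorted(ds.annotations):
            for term in sorted(ds.annotations[gene]):
                handle.write(f"{gene}\t{term}\n")
    with open(paths["truth"], "w") as handle:
        json.dump(
            {
                "enriched_terms": sorted(ds.enriched_terms),
                "disease_genes": sorted(ds.disease_genes),
                "config": dataclasses.asdict(ds.config),
            },
            handle,
            indent=2,
        )
    return paths


def read_known_genes(path) -> set[str]:
    """Read a one-gene-per-line known disease-gene file."""
    out: set[str] = set()
    with open(path) as handle:
        for raw in handle:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.add(line)
    if not out:
        raise ValueError(f"no genes in {path}")
    return out
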