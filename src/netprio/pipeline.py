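"""End-to-end pipeline: simulate/load -> network -> ranking -> enrichment ->
prediction -> rank-bin validation.

`run_pipeline` is the in-memory engine; `run_all` adds file outputs (network
TSV, precision table, per-set gene lists, summary JSON, run log).  All stage
defaults mirror the analysis protocol: interaction score cutoff 0.63,
candidate-gene score cutoff 1.0, top fractions 2/5/7/10%, enrichment p < 0.001,
term-size bounds 3..50, top 20% of terms per namespace, Lin similarity 0.7 for
redundancy pruning, pathway p < 0.01, ten rank bins.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from . import centrality as ct
from . import enrichment as en
from . import network as nw
from . import prediction as pr
from . import simulate as sim
from . import validation as va

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    score_cutoff: float = 0.63
    gene_cutoff: float = 1.0
    measures: tuple[str, ...] = ct.CANONICAL_MEASURES
    prune_threshold: float = 1.0
    fractions: tuple[float, ...] = (0.02, 0.05, 0.07, 0.10)
    set_a_fraction: float = 0.05
    top_policy: str = "round"
    rounding: str = "half-up"
    enrich_p: float = 0.001
    min_term_genes: int = 3
    max_term_genes: int = 50
    top_term_fraction: float = 0.20
    per_namespace: bool = True
    sim_method: str = "lin"
    sim_threshold: float = 0.7
    ora_p: float = 0.01
    n_bins: int = 10
    community_algorithm: str = "louvain"
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    net: nx.Graph
    topology: nw.TopologySummary
    table: ct.CentralityTable
    rho: "object"  # measure x measure DataFrame
    retained_measures: list[str]
    consensus: ct.ConsensusRanking
    precision_rows: list[pr.PrecisionRow]
    criteria: dict[str, dict]  # three term-selection criteria summaries
    enrichment_results: list[en.EnrichmentResult]
    surviving_terms: list[en.EnrichmentResult]
    sets: pr.PredictionSets
    trend: va.BinTrend | None
    summary: dict = field(default_factory=dict)


def _criterion_summary(
    label: str,
    results: Sequence[en.EnrichmentResult],
    ann: en.AnnotationMap,
    net: nx.Graph,
    known_in_net: set[str],
    rounding: str,
) -> dict:
    genes = en.terms_to_genes(results, ann, net)
    row = pr.precision(sorted(genes), known_in_net, label=label, mode=rounding)
    return {
        "criterion": label,
        "n_terms": len(results),
        "n_genes": len(genes),
        "known_genes": row.hits,
        "precision": row.precision,
        "genes": genes,
    }


def run_pipeline(
    cfg: PipelineConfig,
    interactions: Sequence[nw.ScoredInteraction],
    gene_scores: Mapping[str, float],
    known_genes: set[str],
    ann: en.AnnotationMap,
    associations: Mapping[str, int] | None = None,
    synthetic_cfg: sim.SyntheticConfig | None = None,
    compute_topology: bool = True,
) -> PipelineResult:
    """Run every analysis stage on in-memory inputs.

    When ``associations`` is None and ``synthetic_cfg`` is given, disease
    counts are drawn from the generator against the computed consensus;
    when both are None the rank-bin validation stage is skipped.
    """
    universe = {g for g, s in gene_scores.items() if s >= cfg.gene_cutoff}
    if not universe:
        raise ValueError("no genes pass the candidate score cutoff")
    net = nw.build_network(interactions, universe, cfg.score_cutoff)
    topology = (
        nw.summarize_topology(net, seed=cfg.seed, community_algorithm=cfg.community_algorithm)
        if compute_topology
        else None
    )
    table = ct.compute_centralities(net, cfg.measures)
    rho = ct.rank_correlation_matrix(table.fractional_ranks)
    retained = ct.prune_redundant_measures(rho, cfg.prune_threshold)
    consensus = ct.consensus_ranking(table.ordinal_ranks[retained])
    known_in_net = set(known_genes) & set(net.nodes())
    precision_rows = pr.precision_table(
        table.ordinal_ranks[retained],
        consensus,
        known_in_net,
        cfg.fractions,
        policy=cfg.top_policy,
        mode=cfg.rounding,
    )

    # two-list enrichment: disease genes against the candidate universe
    background = set(universe) | set(known_genes & set(gene_scores))
    target = set(known_genes) & background
    enr = en.enrich_two_list(target, background, ann, cfg.enrich_p)
    c1 = en.filter_by_term_size(enr, cfg.min_term_genes, cfg.max_term_genes)
    c2 = en.select_top_terms(enr, cfg.top_term_fraction, cfg.per_namespace)
    c3 = en.prune_redundant_terms(c2, ann.dag, ann.ic, cfg.sim_threshold, cfg.sim_method)
    criteria = {
        "term_size": _criterion_summary("term_size", c1, ann, net, known_in_net, cfg.rounding),
        "top_fraction": _criterion_summary(
            "top_fraction", c2, ann, net, known_in_net, cfg.rounding
        ),
        "pruned": _criterion_summary("pruned", c3, ann, net, known_in_net, cfg.rounding),
    }
    set_c_genes = criteria["pruned"]["genes"]
    set_a = ct.select_top_fraction(consensus, cfg.set_a_fraction, policy=cfg.top_policy)
    sets = pr.define_sets(set_a, known_in_net, set_c_genes, net)

    trend = None
    if associations is None and synthetic_cfg is not None:
        associations = sim.simulate_disease_counts(consensus, synthetic_cfg)
    if associations is not None:
        bins = va.bin_by_rank(consensus, cfg.n_bins)
        trend = va.disease_trend(bins, associations)

    summary = {
        "config_hash": cfg.config_hash(),
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "topology": dataclasses.asdict(topology) if topology else None,
        "retained_measures": retained,
        "n_known_in_network": len(known_in_net),
        "base_rate_pct": round(100.0 * len(known_in_net) / net.number_of_nodes(), 2),
        "precision": [dataclasses.asdict(r) for r in precision_rows],
        "criteria": {
            k: {kk: vv for kk, vv in v.items() if kk != "genes"}
            for k, v in criteria.items()
        },
        "sets": {
            "A": len(sets.set_a),
            "B": len(sets.set_b),
            "C": len(sets.set_c),
            "D": len(sets.set_d),
            "E": len(sets.set_e),
            "F": len(sets.set_f),
            "G": len(sets.set_g),
        },
        "candidates": sorted(sets.set_d),
        "trend": dataclasses.asdict(trend) if trend else None,
    }
    return PipelineResult(
        net=net,
        topology=topology,
        table=table,
        rho=rho,
        retained_measures=retained,
        consensus=consensus,
        precision_rows=precision_rows,
        criteria=criteria,
        enrichment_results=enr,
        surviving_terms=c3,
        sets=sets,
        trend=trend,
        summary=summary,
    )


def run_all(
    cfg: PipelineConfig,
    out_dir,
    synthetic_cfg: sim.SyntheticConfig | None = None,
    input_paths: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the pipeline and write all artifacts under ``out_dir``.

    Inputs come either from the synthetic generator (``synthetic_cfg``) or
    from files (``input_paths`` with keys edges, genes, known, obo,
    annotations and optionally associations, dialect).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    header = f"produced by netprio run-all; config sha256/12={cfg.config_hash()}"
    associations = None
    if synthetic_cfg is not None:
        ds = sim.generate_dataset(synthetic_cfg)
        sim.write_dataset(ds, out / "inputs", header=header)
        interactions = ds.interactions
        gene_scores = ds.gene_scores
        known = set(ds.disease_genes)
        ann = en.build_annotation_map(ds.annotations, ds.dag)
    elif input_paths is not None:
        dialect = input_paths.get("dialect", "simple3col")
        interactions = nw.read_interactions(input_paths["edges"], dialect)
        gene_scores = _read_gene_scores(input_paths["genes"])
        known = sim.read_known_genes(input_paths["known"])
        dag = en.read_obo(input_paths["obo"])
        ann = en.read_annotations(input_paths["annotations"], dag)
        if "associations" in input_paths:
            associations = va.read_associations(input_paths["associations"])
    else:
        raise ValueError("provide either synthetic_cfg or input_paths")

    result = run_pipeline(
        cfg,
        interactions,
        gene_scores,
        known,
        ann,
        associations=associations,
        synthetic_cfg=synthetic_cfg,
    )
    nw.write_network(result.net, out / "network.tsv", header=header)
    frame = pr.precision_table_frame(result.precision_rows)
    with open(out / "precision_table.tsv", "w") as handle:
        handle.write(f"# {header}\n")
        frame.to_csv(handle, sep="\t", index=False)
    sets_dir = out / "sets"
    sets_dir.mkdir(exist_ok=True)
    for name in "abcdefg":
        genes = getattr(result.sets, f"set_{name}")
        with open(sets_dir / f"set_{name.upper()}.txt", "w") as handle:
            handle.write(f"# {header}\n")
            for gene in sorted(genes):
                handle.write(f"{gene}\n")
    with open(out / "summary.json", "w") as handle:
        json.dump(result.summary, handle, indent=2, default=str)
    with open(out / "run.log", "w") as handle:
        handle.write(f"# {header}\n")
        handle.write(f"elapsed_seconds: {time.time() - t0:.1f}\n")
        handle.write(f"pipeline_config: {json.dumps(dataclasses.asdict(cfg))}\n")
        if synthetic_cfg is not None:
            handle.write(f"synthetic_config: {json.dumps(dataclasses.asdict(synthetic_cfg))}\n")
    return result


def _read_gene_scores(path) -> dict[str, float]:
    scores: dict[str, float] = {}
    for _, line in nw._iter_data_lines(path):
        cols = line.split("\t")
        if len(cols) >= 2:
            try:
                scores[cols[0].strip()] = float(cols[1])
            except ValueError:
                continue
    if not scores:
        raise ValueError(f"no gene scores in {path}")
    return scores
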