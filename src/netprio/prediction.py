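"""Candidate-gene set logic and precision tables.

A candidate gene must be top-ranked in the network (Set A), belong to a
significantly enriched ontology term (Set C) and not already be a known
disease gene (Set B): Set D = (A intersect C) minus B.  Sets E, F and G are
diagnostics recording which known genes are recovered by ranking, by
enrichment, or by both.  Precision is the percentage of a selected list that
belongs to the known set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .centrality import ConsensusRanking, select_top_fraction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionSets:
    set_a: frozenset[str]
    set_b: frozenset[str]
    set_c: frozenset[str]
    set_d: frozenset[str]  # (A & C) - B : predicted candidates
    set_e: frozenset[str]  # B & A
    set_f: frozenset[str]  # B & C
    set_g: frozenset[str]  # B & A & C


@dataclass(frozen=True)
class PrecisionRow:
    label: str
    cutoff: float
    hits: int
    total: int
    precision: float  # percentage, reported to 2 decimals


def define_sets(
    consensus_top: Iterable[str],
    known: set[str],
    enriched_genes: set[str],
    net: nx.Graph,
) -> PredictionSets:
    """Assemble Sets A-G from the top-ranked list, known genes and enriched genes.

    Known genes may contain entries outside the network; Set B is their
    intersection with the network nodes.
    """
    nodes = set(net.nodes())
    set_a = frozenset(consensus_top) & nodes
    set_b = frozenset(known) & nodes
    set_c = frozenset(enriched_genes) & nodes
    if not set_a:
        raise ValueError("Set A (top-ranked genes) is empty")
    if not set_c:
        raise ValueError("Set C (enriched-term genes) is empty")
    set_d = (set_a & set_c) - set_b
    if not set_d:
        logger.warning("no candidate genes: A and C share no gene outside B")
    return PredictionSets(
        set_a=set_a,
        set_b=set_b,
        set_c=set_c,
        set_d=frozenset(set_d),
        set_e=set_b & set_a,
        set_f=set_b & set_c,
        set_g=set_b & set_a & set_c,
    )


def _percent(hits: int, total: int, mode: str) -> float:
    # exact integer arithmetic on hundredths of a percent, then scale
    if mode == "half-up":
        hundredths = (2 * 10000 * hits + total) // (2 * total)
    elif mode == "truncate":
        hundredths = (10000 * hits) // total
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return hundredths / 100.0


def precision(
    selected: Sequence[str],
    known: set[str],
    label: str = "",
    cutoff: float = 0.0,
    mode: str = "half-up",
) -> PrecisionRow:
    """Percentage of the selected gene list that belongs to the known set.

    ``mode`` selects the reporting convention for the two-decimal percentage:
    ``half-up`` rounding (default) or ``truncate``.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected gene list is empty")
    if len(set(selected)) != len(selected):
        raise ValueError("selected gene list contains duplicates")
    hits = len(set(selected) & set(known))
    return PrecisionRow(
        label=label,
        cutoff=cutoff,
        hits=hits,
        total=len(selected),
        precision=_percent(hits, len(selected), mode),
    )


def precision_table(
    ordinal_ranks: pd.DataFrame,
    consensus: ConsensusRanking,
    known: set[str],
    fractions: Sequence[float] = (0.02, 0.05, 0.07, 0.10),
    policy: str = "round",
    mode: str = "half-up",
) -> list[PrecisionRow]:
    """Per-cutoff precision of each measure, the pooled union, and the consensus.

    For each fraction: one row per measure's top-k list, one ``pooled`` row
    for the union of all the measures' top-k lists, and one ``consensus`` row.
    """
    rows: list[PrecisionRow] = []
    for frac in fractions:
        pooled: set[str] = set()
        for measure in ordinal_ranks.columns:
            top = select_top_fraction(ordinal_ranks[measure], frac, policy=policy)
            pooled |= set(top)
            rows.append(precision(top, known, label=str(measure), cutoff=frac, mode=mode))
        rows.append(precision(sorted(pooled), known, label="pooled", cutoff=frac, mode=mode))
        top_consensus = select_top_fraction(consensus, frac, policy=policy)
        rows.append(precision(top_consensus, known, label="consensus", cutoff=frac, mode=mode))
    return rows


def precision_table_frame(rows: Sequence[PrecisionRow]) -> pd.DataFrame:
    """Tabular view of precision rows (one row per list/cutoff)."""
    return pd.DataFrame(
        [
            {
                "list": r.label,
                "cutoff": r.cutoff,
                "hits": r.hits,
                "total": r.total,
                "precision": r.precision,
            }
            for r in rows
        ]
    )
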