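"""Rank-bin disease-association validation.

Genes are pooled by consensus rank into equally sized bins (best-ranked genes
in bin 1), the mean number of associated diseases per gene is computed per
bin, and an ordinary least-squares line of mean count versus bin index
summarizes the trend.  A strongly negative trend with high R^2 indicates that
highly ranked genes carry more disease associations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .centrality import ConsensusRanking


@dataclass(frozen=True)
class BinTrend:
    bin_means: tuple[float, ...]  # bin 1 first
    slope: float
    intercept: float
    r_squared: float


def bin_by_rank(consensus: ConsensusRanking, n_bins: int = 10) -> list[list[str]]:
    """Split the consensus order into contiguous, equally sized rank bins.

    Bin sizes differ by at most one; the remainder goes to the earliest
    (best-ranked) bins.  Bin 1 holds the best-ranked genes.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    order = list(consensus.order)
    n = len(order)
    if n < n_bins:
        raise ValueError(f"cannot split {n} genes into {n_bins} bins")
    base, rem = divmod(n, n_bins)
    bins: list[list[str]] = []
    start = 0
    for i in range(n_bins):
        size = base + (1 if i < rem else 0)
        bins.append(order[start : start + size])
        start += size
    return bins


def disease_trend(
    bins: Sequence[Sequence[str]], assoc: Mapping[str, int]
) -> BinTrend:
    """Fit mean diseases-per-gene against bin index by ordinary least squares.

    Genes absent from the association table count as zero.  R^2 is
    1 - SS_res/SS_tot, defined as 0 when all bin means are equal.
    """
    if len(bins) < 2:
        raise ValueError("need at least 2 bins")
    means = np.array(
        [np.mean([assoc.get(g, 0) for g in bin_]) for bin_ in bins], dtype=float
    )
    x = np.arange(1, len(bins) + 1, dtype=float)
    ss_tot = float(((means - means.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return BinTrend(tuple(means), slope=0.0, intercept=float(means.mean()), r_squared=0.0)
    slope, intercept = np.polyfit(x, means, 1)
    resid = means - (slope * x + intercept)
    r_squared = 1.0 - float((resid**2).sum()) / ss_tot
    return BinTrend(tuple(means), float(slope), float(intercept), float(r_squared))


def read_associations(path) -> dict[str, int]:
    """Read a gene-disease association TSV into per-gene counts.

    Two layouts are auto-detected: per-pair rows (gene, disease id — counts
    are aggregated, duplicate pairs deduplicated) and pre-counted rows
    (gene, integer count).  The file is treated as pre-counted when every
    second column parses as an integer.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"association rows need 2 columns: {line!r}")
            rows.append((cols[0].strip(), cols[1].strip()))
    if not rows:
        return {}

    def _as_int(s: str) -> int | None:
        try:
            return int(s)
        except ValueError:
            return None

    if all(_as_int(v) is not None for _, v in rows):
        counts: dict[str, int] = {}
        for gene, v in rows:
            counts[gene] = counts.get(gene, 0) + int(v)
        return counts
    pairs = {(g, d) for g, d in rows}
    counts = {}
    for gene, _ in pairs:
        counts[gene] = counts.get(gene, 0) + 1
    return counts
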