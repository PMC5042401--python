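"""Relating the peptidome to gene-level measurements of its precursors.

Peptide-yielding genes are compared against external gene-level tables:
abundance rankings (RNA-seq FPKM or proteomic copy-number estimates) binned
into rank deciles, protein half-life distributions (values capped at 100 h
by the upstream turnover study), and precursor length statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import ProteinRecord

__all__ = [
    "AbundanceTable",
    "BinCounts",
    "HalfLifeStats",
    "rank_bin",
    "half_life_stats",
    "length_stats",
    "min_proteins_covering",
]

HALF_LIFE_CAP_H = 100.0


@dataclass(frozen=True)
class AbundanceTable:
    """Gene -> non-negative abundance value, in input order (ties keep it)."""

    genes: tuple[str, ...]
    values: tuple[float, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.values):
            raise ValueError("genes and values differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in abundance table")
        for v in self.values:
            if not np.isfinite(v):
                raise ValueError("abundance values must be finite")

    @staticmethod
    def from_mapping(values: Mapping[str, float], source_label: str = ""):
        return AbundanceTable(
            tuple(values.keys()), tuple(float(v) for v in values.values()), source_label
        )

    def ranked_genes(self) -> list[str]:
        """Genes by descending value; ties keep input order (stable sort)."""
        order = np.argsort([-v for v in self.values], kind="stable")
        return [self.genes[i] for i in order]


@dataclass(frozen=True)
class BinCounts:
    """Hit counts per rank bin, plus an overflow bucket.

    ``bins[i]`` is ``((lo_rank, hi_rank), hits)``; ``overflow`` counts hit
    genes absent from the table or ranked below the last bin.  Conservation:
    the bin hits plus overflow sum to the number of distinct hit genes.
    """

    bin_size: int
    bins: tuple[tuple[tuple[int, int], int], ...]
    overflow: int
    n_hits: int


@dataclass(frozen=True)
class HalfLifeStats:
    median_h: float
    frac_le_3h: float
    frac_ge_cap: float
    percentile_curve: tuple[tuple[float, float], ...]
    n: int
    n_missing: int = 0


def rank_bin(
    table: AbundanceTable,
    hits: Sequence[str],
    bin_size: int,
    n_bins: int,
) -> BinCounts:
    """Count peptidome genes per abundance-rank bin.

    Genes are ranked by descending value; bin i covers ranks
    ``[(i-1)*bin_size + 1, i*bin_size]``.  Duplicate hit genes are collapsed
    (each gene judged once); hits not in the table, or ranked beyond the
    last bin, fall into ``overflow``.
    """
    if bin_size < 1 or n_bins < 1:
        raise ValueError("bin_size and n_bins must be >= 1")
    unique_hits = list(dict.fromkeys(hits))
    rank_of = {g: i + 1 for i, g in enumerate(table.ranked_genes())}
    counts = [0] * n_bins
    overflow = 0
    for g in unique_hits:
        rank = rank_of.get(g)
        if rank is None or rank > n_bins * bin_size:
            overflow += 1
        else:
            counts[(rank - 1) // bin_size] += 1
    bins = tuple(
        (((i * bin_size) + 1, (i + 1) * bin_size), counts[i]) for i in range(n_bins)
    )
    return BinCounts(bin_size, bins, overflow, len(unique_hits))


def _half_life_summary(hours: np.ndarray, n_missing: int = 0) -> HalfLifeStats:
    pct = np.arange(0, 101, 1)
    curve = tuple(
        (float(p), float(v)) for p, v in zip(pct, np.percentile(hours, pct))
    )
    return HalfLifeStats(
        median_h=float(np.median(hours)),
        frac_le_3h=float(np.mean(hours <= 3.0)),
        frac_ge_cap=float(np.mean(hours >= HALF_LIFE_CAP_H)),
        percentile_curve=curve,
        n=len(hours),
        n_missing=n_missing,
    )


def half_life_stats(
    table: Mapping[str, float], subset: Sequence[str]
) -> tuple[HalfLifeStats, HalfLifeStats]:
    """Half-life summaries for ``subset`` genes and for the full table.

    Values must be positive and are assumed already capped at 100 h on load
    (see :func:`peptidome.io.read_half_life_table`).  Subset genes missing
    from the table are excluded and counted in ``n_missing``.
    """
    all_hours = np.asarray(list(table.values()), dtype=float)
    if len(all_hours) == 0:
        raise ValueError("empty half-life table")
    if np.any(all_hours <= 0):
        raise ValueError("half-lives must be positive")
    sub, missing = [], 0
    for g in dict.fromkeys(subset):
        if g in table:
            sub.append(table[g])
        else:
            missing += 1
    if not sub:
        raise ValueError("no subset gene found in the half-life table")
    return (
        _half_life_summary(np.asarray(sub, dtype=float), missing),
        _half_life_summary(all_hours),
    )


def length_stats(
    proteins: Sequence[ProteinRecord],
) -> tuple[float, float, list[tuple[int, int]]]:
    """Mean and median precursor length, plus the ascending rank curve."""
    if not proteins:
        raise ValueError("no proteins")
    lengths = sorted(p.length for p in proteins)
    mean = float(np.mean(lengths))
    median = float(np.median(lengths))
    return mean, median, [(i + 1, L) for i, L in enumerate(lengths)]


def min_proteins_covering(
    peptide_counts: Mapping[str, int], threshold: float = 0.5
) -> int:
    """Smallest number of proteins accounting for strictly more than
    ``threshold`` of all peptides.

    Proteins are taken in order of descending peptide count, ties broken by
    protein id, and accumulated until the running share exceeds the
    threshold (strict).
    """
    if not peptide_counts:
        raise ValueError("no peptide counts")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    total = sum(peptide_counts.values())
    if total <= 0:
        raise ValueError("total peptide count must be positive")
    ordered = sorted(peptide_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if threshold == 1.0:
        return sum(1 for _, c in ordered if c >= 1)
    acc = 0
    for m, (_, c) in enumerate(ordered, start=1):
        acc += c
        if acc > threshold * total:
            return m
    return len(ordered)
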