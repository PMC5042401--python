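"""Descriptive peptidome statistics.

Amino-acid composition against a proteome background, N-terminal residue
frequencies, acetylation fraction, mass-distribution summaries, tallies of
peptide location within the precursor (N-terminal / C-terminal / internal),
P1 cleavage-site category tables, and categorical tallies of precursor
annotations (intracellular location, function).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    N_TERMINAL_CLASSES,
    CleavageSite,
    P1Category,
    PeptideMatch,
    PeptideRecord,
    ProteinRecord,
    TerminalClass,
    classify_p1,
)

__all__ = [
    "CompositionTable",
    "SizeStats",
    "LocationTally",
    "aa_composition",
    "nterm_residue_freq",
    "acetyl_fraction",
    "size_stats",
    "terminal_tally",
    "cleavage_tally",
    "tally_by_category",
    "background_composition",
    "published_peptidome_residue_counts",
    "dedupe_sequences",
]


@dataclass(frozen=True)
class CompositionTable:
    """Counts and percentages over a categorical domain (residues, classes)."""

    counts: dict[str, int]
    total: int

    @staticmethod
    def from_counts(counts: Mapping[str, int]) -> "CompositionTable":
        total = int(sum(counts.values()))
        if total <= 0:
            raise ValueError("counts sum to zero; nothing to tabulate")
        return CompositionTable(dict(counts), total)

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    @property
    def percents(self) -> dict[str, float]:
        """Percentages rounded to 1 decimal (composition-table style)."""
        return {k: round(100.0 * v / self.total, 1) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts)
        return pd.DataFrame(
            {
                "category": rows,
                "count": [self.counts[r] for r in rows],
                "percent": [self.percents[r] for r in rows],
                "denominator": self.total,
            }
        )


@dataclass(frozen=True)
class SizeStats:
    mean_mass: float
    median_mass: float
    fraction_in_window: float
    window: tuple[float, float]
    n: int


@dataclass(frozen=True)
class LocationTally:
    """Counts and integer-rounded percents per category, with denominator."""

    counts: dict[str, int]
    denominator: int

    @property
    def percents(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {
            k: round(100.0 * v / self.denominator) for k, v in self.counts.items()
        }

    @property
    def fractions(self) -> dict[str, float]:
        if self.denominator == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.denominator for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.counts)
        return pd.DataFrame(
            {
                "category": rows,
                "count": [self.counts[r] for r in rows],
                "percent": [self.percents[r] for r in rows],
                "denominator": self.denominator,
            }
        )


def dedupe_sequences(peptides: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    """One record per bare sequence (first occurrence kept).

    Census denominators count unique peptides; the same sequence observed
    with different modification states collapses to one entry.
    """
    seen: set[str] = set()
    out = []
    for p in peptides:
        if p.sequence not in seen:
            seen.add(p.sequence)
            out.append(p)
    return out


def aa_composition(
    peptides: Sequence[PeptideRecord], dedupe: bool = True
) -> CompositionTable:
    """Residue composition over all residues of all (by default unique) peptides."""
    if not peptides:
        raise ValueError("no peptides")
    if dedupe:
        peptides = dedupe_sequences(peptides)
    counts: dict[str, int] = {}
    for p in peptides:
        for r in p.sequence:
            counts[r] = counts.get(r, 0) + 1
    return CompositionTable.from_counts(counts)


def nterm_residue_freq(
    peptides: Sequence[PeptideRecord], dedupe: bool = True
) -> CompositionTable:
    """Frequency of the residue at position 1; denominator = number of peptides."""
    if not peptides:
        raise ValueError("no peptides")
    if dedupe:
        peptides = dedupe_sequences(peptides)
    counts: dict[str, int] = {}
    for p in peptides:
        r = p.sequence[0]
        counts[r] = counts.get(r, 0) + 1
    return CompositionTable.from_counts(counts)


def acetyl_fraction(peptides: Sequence[PeptideRecord]) -> float:
    """Fraction of peptides carrying an N-terminal acetyl group."""
    if not peptides:
        return 0.0
    return sum(1 for p in peptides if p.n_acetyl) / len(peptides)


def size_stats(
    masses: Sequence[float], window: tuple[float, float] = (900.0, 3000.0)
) -> SizeStats:
    """Mean/median mass and the fraction inside ``window`` (inclusive)."""
    if len(masses) == 0:
        raise ValueError("no masses")
    arr = np.asarray(masses, dtype=float)
    low, high = window
    frac = float(np.mean((arr >= low) & (arr <= high)))
    return SizeStats(
        mean_mass=float(arr.mean()),
        median_mass=float(np.median(arr)),
        fraction_in_window=frac,
        window=(low, high),
        n=len(arr),
    )


def terminal_tally(classes: Iterable[TerminalClass]) -> LocationTally:
    """Tally peptide locations, one class per peptide.

    The three N-terminal classes are reported individually and pooled under
    ``N-term``; percents are rounded to the nearest integer.
    """
    counts = {tc.value: 0 for tc in TerminalClass}
    n = 0
    for tc in classes:
        counts[tc.value] += 1
        n += 1
    counts["N-term"] = sum(counts[tc.value] for tc in N_TERMINAL_CLASSES)
    counts["C-term"] = counts[TerminalClass.C_TERMINAL.value]
    return LocationTally(counts, n)


def cleavage_tally(
    sites_per_peptide: Sequence[Sequence[CleavageSite]],
) -> tuple[LocationTally, LocationTally]:
    """P1-category tables under both denominators in use.

    Returns ``(per_site, per_peptide)``:

    * per_site — all N-side and C-side bonds pooled, each counted once;
    * per_peptide — a peptide counts once in every category for which it has
      at least one qualifying bond (so per-peptide percents can exceed 100 in
      total; the denominator is the number of peptides).
    """
    site_counts = {c.value: 0 for c in P1Category}
    pep_counts = {c.value: 0 for c in P1Category}
    n_sites = 0
    n_peptides = len(sites_per_peptide)
    for sites in sites_per_peptide:
        cats = set()
        for site in sites:
            cat = classify_p1(site.p1)
            site_counts[cat.value] += 1
            n_sites += 1
            cats.add(cat)
        for cat in cats:
            pep_counts[cat.value] += 1
    return (
        LocationTally(site_counts, n_sites),
        LocationTally(pep_counts, n_peptides),
    )


def tally_by_category(
    proteins: Sequence[ProteinRecord], field: str
) -> LocationTally:
    """Tally precursor proteins by annotation (``location`` or ``function``).

    Each protein counts once regardless of how many peptides it yields;
    missing annotations fall into an ``unknown`` bucket.
    """
    if field not in ("location", "function"):
        raise ValueError("field must be 'location' or 'function'")
    counts: dict[str, int] = {}
    for p in proteins:
        value = getattr(p, field) or "unknown"
        counts[value] = counts.get(value, 0) + 1
    return LocationTally(counts, len(proteins))


def background_composition() -> pd.DataFrame:
    """Reference amino-acid composition of intracellular and nuclear yeast
    proteins (percent, mean +/- SD across proteins), from Cedano et al.,
    J Mol Biol 266:594-600 (1997).

    Shipped as a packaged fixture for side-by-side display with peptidome
    compositions; it is survey data, not recomputed here.
    """
    with resources.files("peptidome.data").joinpath(
        "background_composition.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def published_peptidome_residue_counts() -> pd.DataFrame:
    """Residue counts of published intracellular-peptidome compilations:
    297 peptides identified in *S. cerevisiae* and 627 peptides compiled
    from human cell lines (HEK293T, SH-SY5Y, MCF-7, RPMI-8226).

    These printed counts let composition percentages be recomputed without
    redistributing the underlying peptide lists (which accompany the
    original surveys as supplementary downloads).
    """
    with resources.files("peptidome.data").joinpath(
        "peptide_residue_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)
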