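"""Proteome/peptidome domain model.

Peptide-to-protein mapping, classification of peptides by their location
within the precursor protein, cleavage-site extraction and P1 categorization,
monoisotopic mass computation, and the analytic expectation for the fraction
of protein-terminal peptides under uniform fragmentation.

Coordinate convention: all residue coordinates are 1-based and inclusive,
so ``protein.sequence[start-1:end]`` is the matched peptide.  Residue 1 of a
cytosolic protein is the initiator Met.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass

__all__ = [
    "STANDARD_RESIDUES",
    "TERMINUS",
    "WATER_MONO",
    "ACETYL_MONO",
    "OXIDATION_MONO",
    "TMAB_LABEL_MONO",
    "ProteinRecord",
    "PeptideRecord",
    "PeptideMatch",
    "TerminalClass",
    "Side",
    "CleavageSite",
    "P1Category",
    "map_peptide",
    "classify_terminal",
    "cleavage_sites",
    "classify_p1",
    "expected_terminal_fraction",
    "monoisotopic_mass",
]

#: The 20 standard one-letter residue codes.  B/Z/X/U and lowercase are
#: rejected everywhere: silently skipping them would corrupt composition
#: statistics downstream.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Flank marker used when a peptide abuts a protein terminus.
TERMINUS = "-"

# Monoisotopic deltas, computed from atomic monoisotopic masses via
# pyteomics elemental composition (not hard-coded literals).
WATER_MONO: float = _ptmass.calculate_mass(formula="H2O")
ACETYL_MONO: float = _ptmass.calculate_mass(formula="C2H2O")
OXIDATION_MONO: float = _ptmass.calculate_mass(formula="O")

#: Monoisotopic residue masses (without water), from pyteomics.
RESIDUE_MONO: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

_DEUTERIUM_SHIFT = _ptmass.calculate_mass(formula="H[2]") - _ptmass.calculate_mass(
    formula="H"
)

#: Mass added per trimethylammoniumbutyryl (TMAB) tag on a free amine.
#: D0 adds the C7H14NO group; D3/D6/D9 replace 3/6/9 hydrogens by deuterium.
#: These labels are reported for users validating raw peaks; they are NOT
#: included by :func:`monoisotopic_mass`, which reproduces the unlabeled
#: peptide masses of identification tables.
TMAB_LABEL_MONO: dict[str, float] = {
    f"D{k}": _ptmass.calculate_mass(formula="C7H14NO") + k * _DEUTERIUM_SHIFT
    for k in (0, 3, 6, 9)
}


def _check_sequence(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(
            f"{what} contains nonstandard residue code(s) {sorted(bad)}; "
            "only the 20 standard one-letter codes are accepted"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A proteome entry with optional UniProt-style annotations.

    ``mature_start`` is the 1-based index of the mature-protein N-terminus
    for precursors whose signal/pro sequence is removed post-translationally.
    """

    id: str
    gene: str
    sequence: str
    location: str | None = None
    function: str | None = None
    mature_start: int | None = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, f"protein {self.id!r} sequence")
        if self.mature_start is not None and not (
            2 <= self.mature_start <= len(self.sequence)
        ):
            raise ValueError(
                f"mature_start={self.mature_start} outside [2, {len(self.sequence)}]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide with its variable modifications."""

    sequence: str
    n_acetyl: bool = False
    ox_met_positions: tuple[int, ...] = ()
    gene: str = ""
    observed_mass: float | None = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, "peptide sequence")
        object.__setattr__(self, "ox_met_positions", tuple(self.ox_met_positions))
        for pos in self.ox_met_positions:
            if not (1 <= pos <= len(self.sequence)) or self.sequence[pos - 1] != "M":
                raise ValueError(
                    f"ox_met position {pos} does not point at an M in "
                    f"{self.sequence!r}"
                )

    @property
    def mod_signature(self) -> str:
        """Canonical modification key, e.g. ``ac`` / ``ox3;ox7`` / ``''``."""
        parts = []
        if self.n_acetyl:
            parts.append("ac")
        parts.extend(f"ox{p}" for p in sorted(self.ox_met_positions))
        return ";".join(parts)


@dataclass(frozen=True)
class PeptideMatch:
    """An exact occurrence of a peptide within one protein (1-based, inclusive)."""

    peptide: PeptideRecord
    protein_id: str
    start: int
    end: int
    upstream_flank: str
    downstream_flank: str
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates [{self.start}, {self.end}]")
        if len(self.peptide.sequence) != self.end - self.start + 1:
            raise ValueError("coordinate span does not equal peptide length")


class TerminalClass(enum.Enum):
    """Location of a peptide within its precursor (mutually exclusive).

    A peptide that is both N- and C-terminal (e.g. spanning the whole
    protein) is classified N-terminal: the N-terminal rules take precedence.
    """

    N_TERMINAL_WITH_MET = "N_TERMINAL_WITH_MET"
    N_TERMINAL_MET_REMOVED = "N_TERMINAL_MET_REMOVED"
    MATURE_N_TERMINAL = "MATURE_N_TERMINAL"
    C_TERMINAL = "C_TERMINAL"
    INTERNAL = "INTERNAL"


#: TerminalClass members pooled under the "N-term" umbrella of location
#: tallies (initiator-Met present, initiator-Met removed, mature N-terminus).
N_TERMINAL_CLASSES = (
    TerminalClass.N_TERMINAL_WITH_MET,
    TerminalClass.N_TERMINAL_MET_REMOVED,
    TerminalClass.MATURE_N_TERMINAL,
)


class Side(enum.Enum):
    N_SIDE = "N_SIDE"
    C_SIDE = "C_SIDE"


@dataclass(frozen=True)
class CleavageSite:
    """One scissile bond flanking a peptide: P1 | P1'.

    ``side`` says whether the bond produced the peptide's N-terminus
    (N_SIDE: P1 is the upstream flank) or its C-terminus (C_SIDE: P1 is the
    peptide's last residue).  Bonds at protein termini do not exist and are
    never constructed.
    """

    p1: str
    p1_prime: str
    side: Side

    def __post_init__(self) -> None:
        for r in (self.p1, self.p1_prime):
            if r not in STANDARD_RESIDUES:
                raise ValueError(f"cleavage-site residue {r!r} is not standard")


class P1Category(enum.Enum):
    ACIDIC = "ACIDIC"
    BASIC = "BASIC"
    HYDROPHOBIC = "HYDROPHOBIC"
    PRO = "PRO"
    OTHER = "OTHER"


_P1_SETS = {
    P1Category.ACIDIC: frozenset("DE"),
    P1Category.BASIC: frozenset("KR"),
    P1Category.HYDROPHOBIC: frozenset("LMVAFYW"),
    P1Category.PRO: frozenset("P"),
}


def map_peptide(
    peptide: PeptideRecord, proteome: Sequence[ProteinRecord]
) -> list[PeptideMatch]:
    """Locate every exact occurrence of ``peptide`` in ``proteome``.

    Returns one :class:`PeptideMatch` per occurrence, ordered by
    (protein id, start), with flanking residues filled in (``-`` at protein
    termini).  Matching is literal: I and L are distinct, as are all other
    codes.  When the peptide carries a gene annotation, matches to proteins
    of that gene are marked canonical and others not; with no annotation,
    or no match to the annotated gene, all matches are canonical.

    An empty list means the peptide occurs nowhere; callers decide severity.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    matches: list[tuple[str, int, ProteinRecord]] = []
    for protein in proteome:
        pos = protein.sequence.find(peptide.sequence)
        while pos != -1:
            matches.append((protein.id, pos + 1, protein))
            pos = protein.sequence.find(peptide.sequence, pos + 1)
    matches.sort(key=lambda t: (t[0], t[1]))

    gene = peptide.gene
    gene_hit = gene and any(p.gene == gene for _, _, p in matches)
    out = []
    k = len(peptide.sequence)
    for pid, start, protein in matches:
        end = start + k - 1
        up = TERMINUS if start == 1 else protein.sequence[start - 2]
        down = TERMINUS if end == protein.length else protein.sequence[end]
        canonical = (protein.gene == gene) if gene_hit else True
        out.append(
            PeptideMatch(
                peptide=peptide,
                protein_id=pid,
                start=start,
                end=end,
                upstream_flank=up,
                downstream_flank=down,
                canonical=canonical,
            )
        )
    return out


def _check_match(match: PeptideMatch, protein: ProteinRecord) -> None:
    if match.protein_id != protein.id:
        raise ValueError(
            f"match refers to protein {match.protein_id!r}, got {protein.id!r}"
        )
    if protein.sequence[match.start - 1 : match.end] != match.peptide.sequence:
        raise ValueError("match coordinates inconsistent with protein sequence")


def classify_terminal(match: PeptideMatch, protein: ProteinRecord) -> TerminalClass:
    """Classify a peptide's location within its precursor.

    Rules, in precedence order (N-terminal rules first, so a whole-protein
    peptide is N-terminal):

    * start 1 -> N-terminal with the initiator Met;
    * start 2 of a Met-initiated protein -> N-terminal, Met removed;
    * start at the annotated mature-protein N-terminus -> mature N-terminal;
    * end at the protein's last residue -> C-terminal;
    * otherwise internal.
    """
    _check_match(match, protein)
    if match.start == 1:
        return TerminalClass.N_TERMINAL_WITH_MET
    if match.start == 2 and protein.sequence[0] == "M":
        return TerminalClass.N_TERMINAL_MET_REMOVED
    if protein.mature_start is not None and match.start == protein.mature_start:
        return TerminalClass.MATURE_N_TERMINAL
    if match.end == protein.length:
        return TerminalClass.C_TERMINAL
    return TerminalClass.INTERNAL


def cleavage_sites(match: PeptideMatch, protein: ProteinRecord) -> list[CleavageSite]:
    """The scissile bonds that produced this peptide (0, 1 or 2 sites).

    A bond exists on the N side when the peptide does not start at residue 1
    and on the C side when it does not end at the last residue; protein
    termini are not cleavage sites.
    """
    _check_match(match, protein)
    sites = []
    seq = match.peptide.sequence
    if match.start > 1:
        sites.append(CleavageSite(match.upstream_flank, seq[0], Side.N_SIDE))
    if match.end < protein.length:
        sites.append(CleavageSite(seq[-1], match.downstream_flank, Side.C_SIDE))
    return sites


def classify_p1(residue: str) -> P1Category:
    """Category of the residue N-terminal to a scissile bond.

    The three catalytic proteasome subunits prefer acidic (D, E), basic
    (K, R) and hydrophobic (L, M, V, A, F, Y, W) P1 residues; Pro is kept
    separate because Pro-Xaa cleavage is a hallmark of acid hydrolysis
    artifacts; everything else is OTHER.
    """
    if residue not in STANDARD_RESIDUES:
        raise ValueError(f"nonstandard residue code {residue!r}")
    for cat, members in _P1_SETS.items():
        if residue in members:
            return cat
    return P1Category.OTHER


def expected_terminal_fraction(L: int, k: int) -> float:
    """Probability that a uniformly random k-mer window of an L-residue
    protein touches the protein's N- or C-terminus.

    There are ``W = L - k + 1`` windows, of which at most two (the first and
    the last) are terminal; the fraction is ``min(2, W) / W``.  For a typical
    protein (L around 350) and peptide (k around 15) this is below 1%, the
    null expectation against which terminal over-representation is judged.
    """
    if k < 1 or L < 1:
        raise ValueError("L and k must be positive")
    if k > L:
        raise ValueError(f"peptide length k={k} exceeds protein length L={L}")
    windows = L - k + 1
    return min(2, windows) / windows


def monoisotopic_mass(peptide: PeptideRecord | str) -> float:
    """Monoisotopic mass (Da) of an unlabeled peptide.

    Sum of monoisotopic residue masses plus one water, plus 42.01057 Da per
    N-terminal acetyl and 15.99491 Da per oxidized Met.  Isotopic amine tags
    are deliberately not included (identification tables report unlabeled
    masses); see :data:`TMAB_LABEL_MONO` for the label deltas.
    """
    if isinstance(peptide, str):
        peptide = PeptideRecord(sequence=peptide)
    m = sum(RESIDUE_MONO[r] for r in peptide.sequence) + WATER_MONO
    if peptide.n_acetyl:
        m += ACETYL_MONO
    m += OXIDATION_MONO * len(peptide.ox_met_positions)
    return m
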