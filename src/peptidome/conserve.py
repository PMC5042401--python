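"""Ortholog conservation of peptide-covered protein regions.

Orthologous sequences (e.g. yeast/mouse/human copies of one protein) are
globally aligned, the regions of the reference protein covered by observed
peptides are mapped into alignment columns, and percent amino-acid identity
is computed both over the whole protein and restricted to the peptide
region.  Identity counts only columns where *every* row carries the same
residue, out of the reference's residues (a gap in any row is
non-identical), so the within-peptide figure is "identical residues per
reference peptide residue".

Alignment parameters were not dictated by the upstream homology analyses,
so the default scheme (BLOSUM62, affine gap open 10 / extend 0.5) follows
common practice and is recorded with every report; identity figures should
be read as approximations whenever the original alignment tool is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices

from .core import STANDARD_RESIDUES, PeptideMatch, _check_sequence

__all__ = [
    "SubstitutionScheme",
    "PairwiseAlignment",
    "MultiAlignment",
    "ConservationReport",
    "global_align",
    "progressive_align",
    "region_identity",
    "peptide_regions",
    "merge_intervals",
]

GAP = "-"


@dataclass(frozen=True)
class SubstitutionScheme:
    """Symmetric residue substitution scores with affine gap penalties.

    A gap of length g costs ``gap_open + g * gap_extend`` (penalties are
    stored as non-negative numbers and subtracted).  ``simple`` gives the
    textbook linear scheme (gap_open = 0).
    """

    matrix: Mapping[tuple[str, str], float]
    gap_open: float
    gap_extend: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    def score(self, a: str, b: str) -> float:
        return self.matrix[(a, b)]

    @staticmethod
    def simple(match: float = 1.0, mismatch: float = -1.0, gap: float = 1.0):
        matrix = {
            (a, b): (match if a == b else mismatch)
            for a in STANDARD_RESIDUES
            for b in STANDARD_RESIDUES
        }
        return SubstitutionScheme(
            matrix, gap_open=0.0, gap_extend=gap, label=f"match{match}/mis{mismatch}/gap{gap}"
        )

    @staticmethod
    def blosum62(gap_open: float = 10.0, gap_extend: float = 0.5):
        """Default scheme: BLOSUM62 with affine gaps (open 10, extend 0.5)."""
        blosum = substitution_matrices.load("BLOSUM62")
        matrix = {
            (a, b): float(blosum[a, b])
            for a in STANDARD_RESIDUES
            for b in STANDARD_RESIDUES
        }
        return SubstitutionScheme(
            matrix, gap_open=gap_open, gap_extend=gap_extend, label="BLOSUM62/10/0.5"
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    a_gapped: str
    b_gapped: str
    score: float


@dataclass(frozen=True)
class MultiAlignment:
    """Rows of equal-length gapped strings; ungapping a row gives its input."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) > 1:
            raise ValueError("gapped rows differ in length")

    @property
    def columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        for rid, g in self.rows:
            if rid == seq_id:
                return g
        raise KeyError(f"no row with id {seq_id!r}")


@dataclass(frozen=True)
class ConservationReport:
    set_id: str
    peptide_region_length: int
    protein_length: int
    identity_within_peptides: float
    identity_whole: float
    scheme_label: str = ""


# Traceback states / moves.  Preference order on ties: diagonal, then up
# (gap in the second sequence), then left — fixed so output is reproducible.
_DIAG, _UP, _LEFT = 0, 1, 2
_NEG = float("-inf")


def _gotoh(
    a: Sequence[str],
    b: Sequence[str],
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global DP over generic items; returns (score, moves).

    ``score_fn(i, j)`` scores pairing a[i] with b[j] (0-based).  Moves are
    (_DIAG | _UP | _LEFT) from the start of the alignment.
    """
    n, m = len(a), len(b)
    go, ge = gap_open, gap_extend
    # three layers: M (diag), X (gap in b, consumes a), Y (gap in a, consumes b)
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    # pointer[layer][i][j] = predecessor layer chosen (for traceback)
    ptr = [[[0] * (m + 1) for _ in range(n + 1)] for _ in range(3)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -go - i * ge
        ptr[_UP][i][0] = _UP if i > 1 else _DIAG
    for j in range(1, m + 1):
        Y[0][j] = -go - j * ge
        ptr[_LEFT][0][j] = _LEFT if j > 1 else _DIAG
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = score_fn(i - 1, j - 1)
            # diagonal layer: predecessor preference M > X > Y
            best, lay = Mp[j - 1], _DIAG
            if Xp[j - 1] > best:
                best, lay = Xp[j - 1], _UP
            if Yp[j - 1] > best:
                best, lay = Yp[j - 1], _LEFT
            Mi[j] = best + s
            ptr[_DIAG][i][j] = lay
            # up layer (consume a[i-1] against a gap)
            best, lay = Mp[j] - go - ge, _DIAG
            if Xp[j] - ge > best:
                best, lay = Xp[j] - ge, _UP
            if Yp[j] - go - ge > best:
                best, lay = Yp[j] - go - ge, _LEFT
            Xi[j] = best
            ptr[_UP][i][j] = lay
            # left layer (consume b[j-1] against a gap)
            best, lay = Mi[j - 1] - go - ge, _DIAG
            if Xi[j - 1] - go - ge > best:
                best, lay = Xi[j - 1] - go - ge, _UP
            if Yi[j - 1] - ge > best:
                best, lay = Yi[j - 1] - ge, _LEFT
            Yi[j] = best
            ptr[_LEFT][i][j] = lay

    # final state preference: diagonal > up > left
    score, layer = M[n][m], _DIAG
    if X[n][m] > score:
        score, layer = X[n][m], _UP
    if Y[n][m] > score:
        score, layer = Y[n][m], _LEFT

    moves = []
    i, j = n, m
    while i > 0 or j > 0:
        moves.append(layer)
        prev = ptr[layer][i][j]
        if layer == _DIAG:
            i, j = i - 1, j - 1
        elif layer == _UP:
            i -= 1
        else:
            j -= 1
        layer = prev
    moves.reverse()
    return score, moves


def global_align(a: str, b: str, scheme: SubstitutionScheme) -> PairwiseAlignment:
    """Optimal end-to-end alignment of two sequences under ``scheme``.

    Needleman-Wunsch/Gotoh dynamic programming with affine gaps and a fixed
    tie-break (diagonal over up over left) so the traceback is
    bit-reproducible.
    """
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    score, moves = _gotoh(
        a, b, lambda i, j: scheme.score(a[i], b[j]), scheme.gap_open, scheme.gap_extend
    )
    ga, gb = [], []
    i = j = 0
    for mv in moves:
        if mv == _DIAG:
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif mv == _UP:
            ga.append(a[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b[j]); j += 1
    return PairwiseAlignment("".join(ga), "".join(gb), score)


def _profile_score(scheme: SubstitutionScheme, column: Sequence[str], r: str) -> float:
    """Average substitution score of residue r against a profile column;
    a gap in the column contributes -gap_extend."""
    total = 0.0
    for res in column:
        total += -scheme.gap_extend if res == GAP else scheme.score(res, r)
    return total / len(column)


def progressive_align(
    seqs: Sequence[tuple[str, str]], scheme: SubstitutionScheme | None = None
) -> MultiAlignment:
    """Guide-free progressive alignment of 2 or 3 ``(id, sequence)`` pairs.

    The closest pair (highest pairwise alignment score; ties to the earliest
    pair) is aligned first, then the remaining sequence is aligned to the
    two-row profile, with new gaps propagated into both rows.  Row order in
    the result follows input order.  Larger sets are out of scope: import an
    externally computed alignment instead
    (:func:`peptidome.io.read_gapped_fasta`).
    """
    if scheme is None:
        scheme = SubstitutionScheme.blosum62()
    if len(seqs) == 2:
        aln = global_align(seqs[0][1], seqs[1][1], scheme)
        return MultiAlignment(
            ((seqs[0][0], aln.a_gapped), (seqs[1][0], aln.b_gapped))
        )
    if len(seqs) != 3:
        raise ValueError("progressive_align supports exactly 2 or 3 sequences")

    pairs = [(0, 1), (0, 2), (1, 2)]
    alns = {p: global_align(seqs[p[0]][1], seqs[p[1]][1], scheme) for p in pairs}
    best = max(pairs, key=lambda p: alns[p].score)  # max is stable on ties
    i1, i2 = best
    (i3,) = set(range(3)) - {i1, i2}
    pair_aln = alns[best]
    profile = [pair_aln.a_gapped, pair_aln.b_gapped]
    third = seqs[i3][1]

    columns = list(zip(*profile))
    _, moves = _gotoh(
        columns,
        third,
        lambda i, j: _profile_score(scheme, columns[i], third[j]),
        scheme.gap_open,
        scheme.gap_extend,
    )
    new_rows = ["", "", ""]  # in slots i1, i2, i3 build order
    r1, r2, r3 = [], [], []
    ci = tj = 0
    for mv in moves:
        if mv == _DIAG:
            r1.append(profile[0][ci]); r2.append(profile[1][ci]); r3.append(third[tj])
            ci += 1; tj += 1
        elif mv == _UP:  # profile column against gap in third
            r1.append(profile[0][ci]); r2.append(profile[1][ci]); r3.append(GAP)
            ci += 1
        else:  # new gap column inserted into the profile
            r1.append(GAP); r2.append(GAP); r3.append(third[tj])
            tj += 1
    gapped = {i1: "".join(r1), i2: "".join(r2), i3: "".join(r3)}
    return MultiAlignment(tuple((seqs[i][0], gapped[i]) for i in range(3)))


def merge_intervals(
    intervals: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merging overlaps and adjacency."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def peptide_regions(
    matches: Sequence[PeptideMatch],
) -> tuple[list[tuple[int, int]], int]:
    """Merged peptide-covered intervals of one protein and their total span."""
    if matches:
        ids = {m.protein_id for m in matches}
        if len(ids) > 1:
            raise ValueError(f"matches span multiple proteins: {sorted(ids)}")
    merged = merge_intervals([(m.start, m.end) for m in matches])
    total = sum(e - s + 1 for s, e in merged)
    return merged, total


def region_identity(
    aln: MultiAlignment,
    reference_id: str,
    regions: Sequence[tuple[int, int]],
    scheme_label: str = "",
) -> ConservationReport:
    """Percent identity over the whole reference and within peptide regions.

    A column is identical when every row carries the same (non-gap) residue.
    The denominator is the reference's residues (whole protein, or those
    inside the merged regions), so gaps in other rows count against
    identity.  ``regions`` are 1-based inclusive coordinates on the
    *ungapped* reference.
    """
    ref = aln.row(reference_id)
    merged = merge_intervals(regions)
    ref_len = sum(1 for c in ref if c != GAP)
    for s, e in merged:
        if not (1 <= s <= e <= ref_len):
            raise ValueError(f"region [{s}, {e}] outside reference length {ref_len}")
    in_region = [False] * (ref_len + 1)
    for s, e in merged:
        for i in range(s, e + 1):
            in_region[i] = True

    others = [g for rid, g in aln.rows if rid != reference_id]
    whole_ident = whole_total = reg_ident = reg_total = 0
    ref_pos = 0
    for col in range(len(ref)):
        r = ref[col]
        if r == GAP:
            continue
        ref_pos += 1
        identical = all(o[col] == r for o in others)
        whole_total += 1
        whole_ident += identical
        if in_region[ref_pos]:
            reg_total += 1
            reg_ident += identical

    return ConservationReport(
        set_id=reference_id,
        peptide_region_length=reg_total,
        protein_length=ref_len,
        identity_within_peptides=100.0 * reg_ident / reg_total if reg_total else 0.0,
        identity_whole=100.0 * whole_ident / whole_total if whole_total else 0.0,
        scheme_label=scheme_label,
    )
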