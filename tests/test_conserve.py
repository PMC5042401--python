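"""Alignment and conservation tests, including oracle cross-checks."""

import random

import pytest
from Bio import Align

from conftest import brute_force_score, random_sequences
from peptidome.conserve import (
    MultiAlignment,
    SubstitutionScheme,
    global_align,
    merge_intervals,
    peptide_regions,
    progressive_align,
    region_identity,
)
from peptidome.core import PeptideRecord, ProteinRecord, map_peptide

SIMPLE = SubstitutionScheme.simple()  # match +1 / mismatch -1 / gap -1


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("AAG", "AAG", SIMPLE)
        assert aln.score == 3 and aln.a_gapped == aln.b_gapped == "AAG"

    def test_single_gap(self):
        aln = global_align("AAG", "AG", SIMPLE)
        assert aln.score == 1
        assert aln.b_gapped.count("-") == 1

    def test_random_pairs_match_enumeration_oracle(self):
        """DP score equals the exhaustive-enumeration optimum (simple scheme)."""
        rng = random.Random(200)
        seqs = random_sequences(rng, "ACGT", max_len=6, count=40)
        for a, b in zip(seqs[:20], seqs[20:]):
            assert global_align(a, b, SIMPLE).score == pytest.approx(
                brute_force_score(a, b, SIMPLE)
            ), (a, b)

    def test_affine_pairs_match_enumeration_oracle(self):
        scheme = SubstitutionScheme.simple(match=2, mismatch=-1, gap=1)
        affine = SubstitutionScheme(scheme.matrix, gap_open=2.0, gap_extend=0.5)
        rng = random.Random(7)
        seqs = random_sequences(rng, "ACGT", max_len=6, count=30)
        for a, b in zip(seqs[:15], seqs[15:]):
            assert global_align(a, b, affine).score == pytest.approx(
                brute_force_score(a, b, affine)
            ), (a, b)

    def test_scores_match_biopython_reference(self):
        """Independent cross-check against Bio.Align.PairwiseAligner under
        the same affine parameterization (gap of length g costs open + g*ext)."""
        scheme = SubstitutionScheme.blosum62(gap_open=10.0, gap_extend=0.5)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        rng = random.Random(99)
        seqs = random_sequences(rng, "ACDEFGHIKLMNPQRSTVWY", max_len=25, count=20)
        for a, b in zip(seqs[:10], seqs[10:]):
            assert global_align(a, b, scheme).score == pytest.approx(
                aligner.score(a, b)
            ), (a, b)

    def test_traceback_round_trip(self):
        rng = random.Random(11)
        for a, b in zip(random_sequences(rng, "ACDEFG", 12, 10),
                        random_sequences(rng, "ACDEFG", 12, 10)):
            aln = global_align(a, b, SIMPLE)
            assert aln.a_gapped.replace("-", "") == a
            assert aln.b_gapped.replace("-", "") == b
            assert len(aln.a_gapped) == len(aln.b_gapped)

    def test_nonstandard_rejected(self):
        with pytest.raises(ValueError):
            global_align("AXG", "AAG", SIMPLE)


class TestProgressiveAlign:
    def test_identical_triple_gap_free(self):
        aln = progressive_align(
            [("y", "MKAVD"), ("m", "MKAVD"), ("h", "MKAVD")], SIMPLE
        )
        assert all(g == "MKAVD" for _, g in aln.rows)

    def test_third_row_gains_gap(self):
        aln = progressive_align([("a", "AAG"), ("b", "AAG"), ("c", "AG")], SIMPLE)
        assert aln.columns == 3
        assert aln.row("a") == "AAG" and aln.row("b") == "AAG"
        assert aln.row("c").replace("-", "") == "AG"
        assert aln.row("c").count("-") == 1

    def test_two_sequences(self):
        aln = progressive_align([("a", "MKV"), ("b", "MKV")], SIMPLE)
        assert [rid for rid, _ in aln.rows] == ["a", "b"]

    def test_round_trip_random_triples(self):
        rng = random.Random(21)
        for _ in range(15):
            seqs = [(f"s{i}", s) for i, s in
                    enumerate(random_sequences(rng, "ACDEFGHIK", 15, 3))]
            aln = progressive_align(seqs, SIMPLE)
            for (sid, original), (rid, gapped) in zip(seqs, aln.rows):
                assert rid == sid
                assert gapped.replace("-", "") == original

    def test_row_order_follows_input(self):
        aln = progressive_align([("z", "MKV"), ("a", "MKVA"), ("m", "KVA")], SIMPLE)
        assert [rid for rid, _ in aln.rows] == ["z", "a", "m"]

    def test_more_than_three_unsupported(self):
        with pytest.raises(ValueError):
            progressive_align([("a", "MK")] * 4, SIMPLE)


class TestRegionIdentity:
    def test_identical_triple_full_identity(self):
        aln = MultiAlignment((("y", "MKAVD"), ("m", "MKAVD"), ("h", "MKAVD")))
        rep = region_identity(aln, "y", [(2, 4)])
        assert rep.identity_whole == 100.0
        assert rep.identity_within_peptides == 100.0

    def test_column_by_column_count(self):
        aln = MultiAlignment((("y", "AAG"), ("m", "AAG"), ("h", "ACG")))
        rep = region_identity(aln, "y", [(1, 2)])
        assert rep.identity_whole == pytest.approx(200 / 3)
        assert rep.identity_within_peptides == 50.0
        assert rep.peptide_region_length == 2

    def test_disjoint_alphabets_zero(self):
        aln = MultiAlignment((("y", "AAA"), ("m", "GGG"), ("h", "CCC")))
        rep = region_identity(aln, "y", [(1, 3)])
        assert rep.identity_whole == 0.0

    def test_gap_in_other_row_counts_against_identity(self):
        aln = MultiAlignment((("y", "MKV"), ("m", "M-V")))
        rep = region_identity(aln, "y", [(1, 3)])
        assert rep.identity_whole == pytest.approx(200 / 3)

    def test_whole_protein_region_equals_whole_identity(self):
        aln = progressive_align(
            [("y", "MKAVDQW"), ("m", "MKAVDW"), ("h", "MKVDQW")],
            SubstitutionScheme.blosum62(),
        )
        ref_len = len(aln.row("y").replace("-", ""))
        rep = region_identity(aln, "y", [(1, ref_len)])
        assert rep.identity_within_peptides == rep.identity_whole

    def test_missing_reference_rejected(self):
        aln = MultiAlignment((("y", "MKV"), ("m", "MKV")))
        with pytest.raises(KeyError):
            region_identity(aln, "nope", [])


class TestPeptideRegions:
    def _matches(self, protein, windows):
        out = []
        for s, e in windows:
            pep = PeptideRecord(protein.sequence[s - 1:e])
            out.append(next(m for m in map_peptide(pep, [protein])
                            if m.start == s))
        return out

    def test_overlap_merged(self):
        p = ProteinRecord(id="P", gene="G", sequence="M" + "ACDEFGHIKLMNPQR" * 2)
        regions, total = peptide_regions(self._matches(p, [(1, 10), (5, 15)]))
        assert regions == [(1, 15)] and total == 15

    def test_single_match(self):
        p = ProteinRecord(id="P", gene="G", sequence="MACDEFGHIK")
        regions, total = peptide_regions(self._matches(p, [(3, 8)]))
        assert regions == [(3, 8)] and total == 6

    def test_adjacent_merged_two_nterminal_peptides(self):
        """Two abutting N-terminal peptides cover one contiguous region
        (e.g. residues 1-12 and 13-26 giving 26 covered residues)."""
        p = ProteinRecord(id="P", gene="G",
                         sequence="MSQNAFDKVAEKVSSLPQNVVARAQSAKPGA")
        regions, total = peptide_regions(self._matches(p, [(1, 12), (13, 26)]))
        assert regions == [(1, 26)] and total == 26

    def test_multiple_proteins_rejected(self):
        p1 = ProteinRecord(id="P1", gene="G", sequence="MACDEF")
        p2 = ProteinRecord(id="P2", gene="G", sequence="MACDEF")
        m1 = self._matches(p1, [(1, 3)])[0]
        m2 = self._matches(p2, [(1, 3)])[0]
        with pytest.raises(ValueError):
            peptide_regions([m1, m2])


class TestMergeIntervals:
    def test_idempotent_and_order_independent(self):
        intervals = [(5, 9), (1, 3), (8, 12), (20, 22)]
        merged = merge_intervals(intervals)
        assert merged == [(1, 3), (5, 12), (20, 22)]
        assert merge_intervals(merged) == merged
        assert merge_intervals(list(reversed(intervals))) == merged

    def test_adjacency_merges(self):
        assert merge_intervals([(1, 4), (5, 8)]) == [(1, 8)]

    def test_empty(self):
        assert merge_intervals([]) == []
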