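"""Domain-model tests: mapping, terminal classes, cleavage sites, masses."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptidome.core import (
    TERMINUS,
    WATER_MONO,
    CleavageSite,
    P1Category,
    PeptideRecord,
    ProteinRecord,
    Side,
    TerminalClass,
    classify_p1,
    classify_terminal,
    cleavage_sites,
    expected_terminal_fraction,
    map_peptide,
    monoisotopic_mass,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=30)


class TestMapPeptide:
    def test_whole_protein_match(self):
        protein = ProteinRecord(id="P", gene="G", sequence="MKV")
        (m,) = map_peptide(PeptideRecord("MKV"), [protein])
        assert (m.start, m.end) == (1, 3)
        assert m.upstream_flank == TERMINUS and m.downstream_flank == TERMINUS

    def test_internal_match_with_flanks(self, adh1_host):
        (m,) = map_peptide(PeptideRecord("STLPEIYEK", gene="ADH1"), [adh1_host])
        assert (m.start, m.end) == (3, 11)
        assert (m.upstream_flank, m.downstream_flank) == ("A", "G")

    def test_overlapping_occurrences(self):
        protein = ProteinRecord(id="P", gene="G", sequence="AAAA")
        ms = map_peptide(PeptideRecord("AAA"), [protein])
        assert [(m.start, m.end) for m in ms] == [(1, 3), (2, 4)]

    def test_no_occurrence_returns_empty(self, small_proteome):
        assert map_peptide(PeptideRecord("WWWWW"), small_proteome) == []

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            map_peptide(PeptideRecord("AK"), [])

    def test_gene_annotation_marks_canonical(self):
        proteome = [
            ProteinRecord(id="P1", gene="TDH1", sequence="MSTGVFKEL"),
            ProteinRecord(id="P2", gene="TDH3", sequence="MSTGVFKELA"),
        ]
        ms = map_peptide(PeptideRecord("STGVFKEL", gene="TDH3"), proteome)
        assert [m.canonical for m in ms] == [False, True]

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(protein_seq=st.text(alphabet=AA, min_size=2, max_size=60),
           data=st.data())
    def test_round_trip_slicing(self, protein_seq, data):
        """Slicing the protein at [start, end] reproduces the peptide."""
        protein = ProteinRecord(id="P", gene="G", sequence=protein_seq)
        start = data.draw(st.integers(1, len(protein_seq)))
        end = data.draw(st.integers(start, len(protein_seq)))
        pep = PeptideRecord(protein_seq[start - 1:end])
        for m in map_peptide(pep, [protein]):
            assert protein.sequence[m.start - 1:m.end] == pep.sequence


class TestClassifyTerminal:
    def _match(self, protein, start, end):
        return map_peptide(
            PeptideRecord(protein.sequence[start - 1:end]), [protein]
        )[0] if start == 1 else next(
            m for m in map_peptide(
                PeptideRecord(protein.sequence[start - 1:end]), [protein]
            ) if m.start == start
        )

    def test_start_one_is_nterminal_with_met(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQW")
        m = self._match(p, 1, 3)
        assert classify_terminal(m, p) is TerminalClass.N_TERMINAL_WITH_MET

    def test_met_removed(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQW")
        m = self._match(p, 2, 4)
        assert classify_terminal(m, p) is TerminalClass.N_TERMINAL_MET_REMOVED

    def test_cterminal(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQW")
        m = self._match(p, 4, 6)
        assert classify_terminal(m, p) is TerminalClass.C_TERMINAL

    def test_internal(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQW")
        m = self._match(p, 3, 5)
        assert classify_terminal(m, p) is TerminalClass.INTERNAL

    def test_whole_protein_precedence_is_nterminal(self):
        p = ProteinRecord(id="P", gene="G", sequence="MKV")
        m = self._match(p, 1, 3)
        assert classify_terminal(m, p) is TerminalClass.N_TERMINAL_WITH_MET

    def test_mature_start(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQWERT", mature_start=4)
        m = self._match(p, 4, 6)
        assert classify_terminal(m, p) is TerminalClass.MATURE_N_TERMINAL

    def test_protein_mismatch_rejected(self):
        p = ProteinRecord(id="P", gene="G", sequence="MAVKQW")
        other = ProteinRecord(id="Q", gene="G", sequence="MAVKQW")
        m = self._match(p, 2, 4)
        with pytest.raises(ValueError):
            classify_terminal(m, other)


class TestCleavageSites:
    def test_internal_has_two_sites(self):
        p = ProteinRecord(id="P", gene="G", sequence="MKAVSYAGW")
        m = next(x for x in map_peptide(PeptideRecord("AVSYA"), [p]))
        sites = cleavage_sites(m, p)
        assert sites == [
            CleavageSite("K", "A", Side.N_SIDE),
            CleavageSite("A", "G", Side.C_SIDE),
        ]

    def test_whole_protein_no_sites(self):
        p = ProteinRecord(id="P", gene="G", sequence="MKV")
        (m,) = map_peptide(PeptideRecord("MKV"), [p])
        assert cleavage_sites(m, p) == []

    def test_nterminal_peptide_one_cside(self):
        p = ProteinRecord(id="P", gene="G", sequence="MKVAV")
        m = next(x for x in map_peptide(PeptideRecord("MKV"), [p]))
        sites = cleavage_sites(m, p)
        assert len(sites) == 1 and sites[0].side is Side.C_SIDE


class TestClassifyP1:
    @pytest.mark.parametrize(
        "residue,category",
        [("K", P1Category.BASIC), ("R", P1Category.BASIC),
         ("D", P1Category.ACIDIC), ("E", P1Category.ACIDIC),
         ("W", P1Category.HYDROPHOBIC), ("L", P1Category.HYDROPHOBIC),
         ("M", P1Category.HYDROPHOBIC), ("V", P1Category.HYDROPHOBIC),
         ("A", P1Category.HYDROPHOBIC), ("F", P1Category.HYDROPHOBIC),
         ("Y", P1Category.HYDROPHOBIC),
         ("P", P1Category.PRO),
         ("G", P1Category.OTHER), ("S", P1Category.OTHER)],
    )
    def test_examples(self, residue, category):
        assert classify_p1(residue) is category

    def test_partition(self):
        """Every standard residue maps to exactly one category."""
        assert sorted(classify_p1(r).value for r in AA).count("OTHER") == 8
        assert len([classify_p1(r) for r in AA]) == 20

    def test_nonstandard_rejected(self):
        for bad in ("B", "X", "U", "a"):
            with pytest.raises(ValueError):
                classify_p1(bad)


class TestExpectedTerminalFraction:
    def test_typical_protein(self):
        assert expected_terminal_fraction(350, 15) == pytest.approx(2 / 336)

    def test_whole_protein_window(self):
        assert expected_terminal_fraction(15, 15) == 1.0

    def test_two_windows_both_terminal(self):
        assert expected_terminal_fraction(16, 15) == 1.0

    def test_k_exceeding_L_rejected(self):
        with pytest.raises(ValueError):
            expected_terminal_fraction(10, 11)


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [("G", 75.03203), ("AG", 146.06914)],
    )
    def test_frozen_values(self, seq, expected):
        assert monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-4)

    def test_acetyl_delta(self):
        plain = monoisotopic_mass("G")
        ac = monoisotopic_mass(PeptideRecord("G", n_acetyl=True))
        assert ac - plain == pytest.approx(42.01057, abs=1e-4)
        assert ac == pytest.approx(117.04260, abs=1e-4)

    def test_ox_met_delta(self):
        plain = monoisotopic_mass("AMK")
        ox = monoisotopic_mass(PeptideRecord("AMK", ox_met_positions=(2,)))
        assert ox - plain == pytest.approx(15.99491, abs=1e-4)

    def test_ox_position_must_be_met(self):
        with pytest.raises(ValueError):
            PeptideRecord("AAK", ox_met_positions=(2,))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(s1=seqs, s2=seqs)
    def test_additivity(self, s1, s2):
        """mass(s1 + s2) = mass(s1) + mass(s2) - water."""
        assert monoisotopic_mass(s1 + s2) == pytest.approx(
            monoisotopic_mass(s1) + monoisotopic_mass(s2) - WATER_MONO, abs=1e-6
        )

    def test_nonstandard_sequence_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("AXK")
        with pytest.raises(ValueError):
            monoisotopic_mass("")
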