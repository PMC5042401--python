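"""Shared fixtures: tiny synthetic proteomes and the exhaustive alignment oracle."""

from __future__ import annotations

import itertools
import random

import pytest

from peptidome.core import PeptideRecord, ProteinRecord


@pytest.fixture
def adh1_host() -> ProteinRecord:
    """Synthetic 12-residue host protein carrying the ADH1 peptide
    STLPEIYEK at residues 3-11 (fixture sequence, not the real ADH1)."""
    return ProteinRecord(id="HOST1", gene="ADH1", sequence="AASTLPEIYEKG")


@pytest.fixture
def small_proteome() -> list[ProteinRecord]:
    return [
        ProteinRecord(id="P1", gene="G1", sequence="MKVAVSKVYAG"),
        ProteinRecord(id="P2", gene="G2", sequence="MAVKDDEEKKLL",
                      location="cytosol", function="metabolism"),
        ProteinRecord(id="P3", gene="G3", sequence="AAAA"),
    ]


def enumerate_alignments(n: int, m: int):
    """All move sequences (0=diag, 1=up, 2=left) aligning lengths n and m."""
    def rec(i, j):
        if i == n and j == m:
            yield ()
            return
        if i < n and j < m:
            for rest in rec(i + 1, j + 1):
                yield (0,) + rest
        if i < n:
            for rest in rec(i + 1, j):
                yield (1,) + rest
        if j < m:
            for rest in rec(i, j + 1):
                yield (2,) + rest
    yield from rec(0, 0)


def score_alignment(a: str, b: str, moves, matrix, gap_open: float,
                    gap_extend: float) -> float:
    """Affine score of one explicit alignment: each maximal gap run of
    length g costs gap_open + g * gap_extend."""
    score = 0.0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == 0:
            score += matrix[(a[i], b[j])]
            i += 1
            j += 1
        else:
            if mv != prev:
                score -= gap_open
            score -= gap_extend
            if mv == 1:
                i += 1
            else:
                j += 1
        prev = mv
    return score


def brute_force_score(a: str, b: str, scheme) -> float:
    """Exhaustive-enumeration optimum: independent oracle for global_align."""
    return max(
        score_alignment(a, b, mv, scheme.matrix, scheme.gap_open, scheme.gap_extend)
        for mv in enumerate_alignments(len(a), len(b))
    )


def random_sequences(rng: random.Random, alphabet: str, max_len: int, count: int):
    return [
        "".join(rng.choice(alphabet) for _ in range(rng.randint(1, max_len)))
        for _ in range(count)
    ]
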