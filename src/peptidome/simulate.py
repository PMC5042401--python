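"""Synthetic proteome / peptidome / intensity-table generator.

Emulates the statistical structure the analysis assumes about an
intracellular peptidome: precursor proteins drawn preferentially from the
abundant end of a log-normal abundance distribution, peptide windows with a
tunable excess of protein-terminal fragments, P1 residue preferences at the
N-side cleavage site, and 4-plex (two control + two treated replicates)
isotopic-label intensities with multiplicative log-normal noise around
known fold changes.

Everything is deterministic under ``(seed, config)``: one root seed spawns
independent child streams for the proteome, the peptidome and the
measurement noise, so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import census
from .core import (
    STANDARD_RESIDUES,
    PeptideMatch,
    PeptideRecord,
    ProteinRecord,
    classify_p1,
    monoisotopic_mass,
)
from .quant import ChannelDesign, Group

__all__ = ["SimConfig", "GroundTruth", "make_proteome", "make_peptidome",
           "make_intensity_tables", "write_ground_truth"]

_RESIDUES = sorted(STANDARD_RESIDUES)


def _default_residue_frequencies() -> dict[str, float]:
    """Residue frequencies of intracellular yeast proteins (survey means,
    renormalized to sum to 1) — a realistic proteome background."""
    bg = census.background_composition()
    raw = dict(zip(bg["residue"], bg["intracellular_percent"]))
    total = sum(raw.values())
    return {r: raw[r] / total for r in _RESIDUES}


def _default_p1_weights() -> dict[str, float]:
    """Relative P1 preferences of proteasome-like cleavage: roughly half of
    sites hydrophobic, over-representation of basic, some acidic, almost
    never Pro."""
    return {"HYDROPHOBIC": 0.50, "BASIC": 0.22, "ACIDIC": 0.11,
            "PRO": 0.005, "OTHER": 0.165}


@dataclass
class SimConfig:
    """Generator settings; the defaults describe a realistic small study.

    * proteome: 500 proteins, lengths ~ truncated normal(480, 300, min 60)
      (right-skew-free stand-in for a yeast-like length distribution),
      residues i.i.d. from intracellular-proteome frequencies, initiator M;
    * peptidome: 300 peptides of length ~ N(15, 4) clipped to [7, 30]
      (masses around 1.6 kDa), precursors drawn with probability
      proportional to a log-normal(0, 1.5) protein abundance;
    * terminal enrichment theta = 0.28: that probability mass is forced onto
      terminal windows (N or C with equal odds), matching the observed
      ~30% terminal excess over the <1% uniform expectation;
    * labeling: 3 runs of the 4-plex design (channels D0/D3/D6/D9, two
      control then two treated), 2 charge states per peptide, multiplicative
      log-normal noise with CV 20%.
    """

    seed: int = 0
    n_proteins: int = 500
    length_distribution: tuple[float, float, int] = (480.0, 300.0, 60)
    residue_frequencies: Mapping[str, float] | None = None
    n_peptides: int = 300
    peptide_length_distribution: tuple[float, float, int, int] = (15.0, 4.0, 7, 30)
    terminal_enrichment: float = 0.28
    p1_weights: Mapping[str, float] | None = None
    abundance_shape: tuple[float, float] = (0.0, 1.5)
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    default_fold: float = 1.0
    noise_cv: float = 0.20
    runs: int = 3
    charge_states: tuple[int, ...] = (2, 3)
    channels: tuple[str, ...] = ("D0", "D3", "D6", "D9")
    acetyl_prob_nterm: float = 0.57
    ox_met_prob: float = 0.05
    #: real identification tables list unique sequences; disable for large
    #: statistical simulations where i.i.d. draws are what is being checked
    unique_sequences: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.terminal_enrichment <= 1.0):
            raise ValueError("terminal_enrichment must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.residue_frequencies is not None:
            s = sum(self.residue_frequencies.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"residue_frequencies sum to {s}, expected 1")

    def child_rngs(self) -> dict[str, np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        names = ("proteome", "peptidome", "noise")
        return {
            name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(names, ss.spawn(len(names)))
        }


@dataclass
class GroundTruth:
    """What the generator actually did, for closing the loop in tests."""

    abundance: dict[str, float] = field(default_factory=dict)  # protein id -> value
    peptide_source: dict[str, str] = field(default_factory=dict)  # seq -> protein id
    peptide_coords: dict[str, tuple[int, int]] = field(default_factory=dict)
    peptide_terminal: dict[str, bool] = field(default_factory=dict)
    peptide_fold: dict[str, float] = field(default_factory=dict)
    #: one entry per draw (sequence, protein id, start, end, terminal flag);
    #: unlike the by-sequence views this never collapses duplicate draws
    draws: list[tuple[str, str, int, int, bool]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "abundance": self.abundance,
                "peptide_source": self.peptide_source,
                "peptide_coords": {k: list(v) for k, v in self.peptide_coords.items()},
                "peptide_terminal": self.peptide_terminal,
                "peptide_fold": self.peptide_fold,
                "draws": [list(d) for d in self.draws],
            },
            indent=1,
            sort_keys=True,
        )


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Draw from N(mean, sd) re-drawing below ``lower`` (vectorized loop)."""
    if sd == 0:
        vals = np.full(size if size else 1, float(mean))
    else:
        vals = rng.normal(mean, sd, size=size if size else 1)
        for _ in range(1000):
            bad = vals < lower
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        else:
            raise ValueError("length bounds infeasible: truncation never satisfied")
    vals = np.maximum(vals, lower)
    return vals if size else float(vals[0])


def make_proteome(config: SimConfig) -> list[ProteinRecord]:
    """Random proteome: truncated-normal lengths, i.i.d. residues, leading Met."""
    rng = config.child_rngs()["proteome"]
    freqs = config.residue_frequencies or _default_residue_frequencies()
    residues = _RESIDUES
    p = np.array([freqs.get(r, 0.0) for r in residues])
    if p.sum() <= 0:
        raise ValueError("residue_frequencies are all zero")
    p = p / p.sum()
    mean, sd, lo = config.length_distribution
    lengths = np.rint(_truncated_normal(rng, mean, sd, lo, size=config.n_proteins))
    proteins = []
    for i, L in enumerate(lengths.astype(int)):
        body = rng.choice(residues, size=L - 1, p=p)
        seq = "M" + "".join(body)
        proteins.append(
            ProteinRecord(id=f"SYN{i:04d}", gene=f"GENE{i:04d}", sequence=seq)
        )
    return proteins


def _draw_window(rng, L, kmean, ksd, kmin, kmax, theta):
    """Window (start, k, forced_terminal) on a length-L protein."""
    hi = min(kmax, L)
    lo = min(kmin, L)
    k = int(round(_truncated_normal(rng, kmean, ksd, lo)))
    k = max(lo, min(k, hi))
    W = L - k + 1
    if theta > 0 and rng.random() < theta:
        start = 1 if rng.random() < 0.5 else W
        return start, k, True
    start = int(rng.integers(1, W + 1))
    return start, k, False


def make_peptidome(
    proteome: Sequence[ProteinRecord], config: SimConfig
) -> tuple[list[PeptideRecord], GroundTruth]:
    """Draw peptides from abundance-weighted precursors.

    With probability theta the window is forced onto a protein terminus
    (N or C, equal odds); otherwise the start is uniform over all windows,
    so theta = 0 reproduces the analytic terminal expectation.  For
    non-N-terminal windows the upstream (P1) residue is accepted by
    rejection sampling against ``p1_weights``; uniform weights (or ``None``)
    disable the preference.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rngs = config.child_rngs()
    rng = rngs["peptidome"]
    mu, sigma = config.abundance_shape
    abundance = rng.lognormal(mu, sigma, size=len(proteome))
    weights = abundance / abundance.sum()
    kmean, ksd, kmin, kmax = config.peptide_length_distribution

    p1w = config.p1_weights
    if p1w is not None:
        wmax = max(p1w.values())
        if wmax <= 0:
            raise ValueError("p1_weights must contain a positive weight")

    truth = GroundTruth(
        abundance={p.id: float(a) for p, a in zip(proteome, abundance)}
    )
    peptides: list[PeptideRecord] = []
    seen: set[str] = set()
    for _ in range(config.n_peptides):
        for _attempt in range(2000):
            pi = int(rng.choice(len(proteome), p=weights))
            protein = proteome[pi]
            start, k, forced = _draw_window(
                rng, protein.length, kmean, ksd, kmin, kmax,
                config.terminal_enrichment,
            )
            if p1w is not None and start > 1:
                cat = classify_p1(protein.sequence[start - 2]).value
                if rng.random() >= p1w.get(cat, 0.0) / wmax:
                    continue
            seq = protein.sequence[start - 1 : start - 1 + k]
            if config.unique_sequences and seq in seen:
                continue
            break
        else:
            raise RuntimeError("could not draw an acceptable peptide window")
        seen.add(seq)
        end = start + k - 1
        n_terminal = start <= 2
        acetyl = bool(n_terminal and rng.random() < config.acetyl_prob_nterm)
        ox = tuple(
            i + 1
            for i, r in enumerate(seq)
            if r == "M" and rng.random() < config.ox_met_prob
        )
        peptides.append(
            PeptideRecord(
                sequence=seq, n_acetyl=acetyl, ox_met_positions=ox,
                gene=protein.gene,
            )
        )
        terminal = bool(start == 1 or end == protein.length)
        truth.peptide_source[seq] = protein.id
        truth.peptide_coords[seq] = (start, end)
        truth.peptide_terminal[seq] = terminal
        truth.peptide_fold[seq] = float(
            config.fold_changes.get(seq, config.default_fold)
        )
        truth.draws.append((seq, protein.id, start, end, terminal))
    return peptides, truth


def make_intensity_tables(
    peptidome: Sequence[PeptideRecord],
    truth: GroundTruth,
    config: SimConfig,
) -> tuple[dict[str, "pd.DataFrame"], dict[str, ChannelDesign]]:
    """Per-run intensity tables for the 4-plex design.

    Base intensity per peptide is its precursor abundance on an arbitrary
    ion-count scale; control channels measure the base, treated channels
    the base times the peptide's true fold change, every measurement
    multiplied by log-normal noise of the configured CV (mean 1), drawn
    independently per run, channel and charge state.
    """
    import pandas as pd  # local import keeps module import light

    rng = config.child_rngs()["noise"]
    cv = config.noise_cv
    if cv > 0:
        s2 = np.log1p(cv * cv)
        sigma = np.sqrt(s2)
        mu_noise = -s2 / 2.0  # unit-mean multiplicative noise
    designs = {
        f"run{r+1}": ChannelDesign.two_by_two(f"run{r+1}", config.channels)
        for r in range(config.runs)
    }
    tables = {}
    for run_id, design in designs.items():
        rows = []
        for pep in peptidome:
            base = truth.abundance[truth.peptide_source[pep.sequence]] * 1e6
            fold = truth.peptide_fold[pep.sequence]
            for z in config.charge_states:
                row = {
                    "run_id": run_id,
                    "sequence": pep.sequence,
                    "mod_signature": pep.mod_signature,
                    "charge": z,
                }
                for ch in design.channels:
                    level = base * (
                        fold if design.group_of[ch] is Group.TREATED else 1.0
                    )
                    if cv > 0:
                        level *= float(rng.lognormal(mu_noise, sigma))
                    row[ch] = level
                rows.append(row)
        tables[run_id] = pd.DataFrame(rows)
    return tables, designs


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
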