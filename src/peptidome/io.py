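"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinates in these files are 1-based and inclusive; ``-`` in a flank
column marks a protein terminus.  FASTA headers may carry a key-value tail
(``>ACC gene=NAME loc=cytosol func=metabolism mature=24``) which is parsed
into the protein annotations when present.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import PeptideRecord, ProteinRecord, TERMINUS
from .enrich import HALF_LIFE_CAP_H, AbundanceTable
from .quant import ChannelDesign, Group, IntensityObservation

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gapped_fasta",
    "read_peptide_table",
    "write_peptide_table",
    "read_intensity_table",
    "observations_from_frame",
    "write_intensity_table",
    "read_design",
    "read_abundance_table",
    "read_half_life_table",
    "read_regions",
]

_HEADER_KEYS = {"gene": "gene", "loc": "location", "func": "function"}


def _parse_header(record: SeqRecord) -> dict:
    fields: dict = {"id": record.id, "gene": record.id}
    for token in record.description.split()[1:]:
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key in _HEADER_KEYS:
            fields[_HEADER_KEYS[key]] = value
        elif key == "mature":
            fields["mature_start"] = int(value)
    return fields


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Proteome / ortholog-set FASTA with optional key-value header tail."""
    proteins = []
    for record in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(record)
        proteins.append(ProteinRecord(sequence=str(record.seq).upper(), **fields))
    if not proteins:
        raise ValueError(f"no FASTA records in {path}")
    return proteins


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    records = []
    for p in proteins:
        desc = [f"gene={p.gene}"]
        if p.location:
            desc.append(f"loc={p.location}")
        if p.function:
            desc.append(f"func={p.function}")
        if p.mature_start is not None:
            desc.append(f"mature={p.mature_start}")
        records.append(
            SeqRecord(Seq(p.sequence), id=p.id, description=" ".join(desc))
        )
    SeqIO.write(records, str(path), "fasta")


def read_gapped_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, gapped sequence) rows of an externally computed alignment."""
    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return rows


PEPTIDE_COLUMNS = [
    "sequence", "n_acetyl", "ox_met", "gene", "protein_id",
    "start", "end", "upstream", "downstream", "mass",
]


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Peptide identification table (TSV, header required).

    Columns: sequence, n_acetyl (0/1), ox_met (semicolon-joined 1-based
    indices, empty allowed), gene, protein_id, start, end, upstream,
    downstream, mass.  Missing start/end means coordinates must be
    recovered by mapping against the proteome.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str}, keep_default_na=True)
    missing = [c for c in ("sequence",) if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} lacks column(s) {missing}")
    return df


def peptide_records(df: pd.DataFrame) -> list[PeptideRecord]:
    """Turn peptide-table rows into :class:`PeptideRecord` objects."""
    records = []
    for _, row in df.iterrows():
        ox_raw = row.get("ox_met", "")
        ox = ()
        if isinstance(ox_raw, str) and ox_raw.strip():
            ox = tuple(int(x) for x in ox_raw.split(";"))
        records.append(
            PeptideRecord(
                sequence=row["sequence"],
                n_acetyl=bool(int(row.get("n_acetyl", 0) or 0)),
                ox_met_positions=ox,
                gene=str(row.get("gene", "") or ""),
            )
        )
    return records


def write_peptide_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_intensity_table(df: pd.DataFrame, path: str | Path) -> None:
    """Intensity TSV: run_id, sequence, mod_signature, charge, one column
    per channel; empty cell = not detected."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_intensity_table(
    path: str | Path, channels: Sequence[str]
) -> list[IntensityObservation]:
    df = pd.read_csv(path, sep="\t")
    required = ["run_id", "sequence", "mod_signature", "charge"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table {path} lacks column(s) {missing}")
    return observations_from_frame(df, channels)


def observations_from_frame(
    df: pd.DataFrame, channels: Sequence[str]
) -> list[IntensityObservation]:
    """Intensity-table rows (in-memory) to observations; NaN cells are ND."""
    observations = []
    for _, row in df.iterrows():
        intensities = {
            ch: float(row[ch])
            for ch in channels
            if ch in df.columns and pd.notna(row[ch])
        }
        if not intensities:
            continue
        mod = row["mod_signature"]
        observations.append(
            IntensityObservation(
                peptide_key=(row["sequence"], "" if pd.isna(mod) else str(mod)),
                run_id=str(row["run_id"]),
                charge=int(row["charge"]),
                intensity_by_channel=intensities,
            )
        )
    return observations


def read_design(path: str | Path) -> dict[str, ChannelDesign]:
    """Labeling design YAML: per run, channel -> {group, replicate}.

    Example::

        runs:
          run1:
            D0: {group: CONTROL, replicate: c1}
            D3: {group: CONTROL, replicate: c2}
            D6: {group: TREATED, replicate: t1}
            D9: {group: TREATED, replicate: t2}
    """
    raw = yaml.safe_load(Path(path).read_text())
    designs = {}
    for run_id, channels in raw["runs"].items():
        names = tuple(channels)
        group_of = {ch: Group[spec["group"]] for ch, spec in channels.items()}
        replicate_of = {
            ch: str(spec.get("replicate", ch)) for ch, spec in channels.items()
        }
        designs[str(run_id)] = ChannelDesign(
            str(run_id), names, group_of, replicate_of
        )
    return designs


def _read_two_column(path: str | Path, value_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene", value_name]
    return df


def read_abundance_table(
    path: str | Path, source_label: str = "", uppercase: bool = True
) -> AbundanceTable:
    """Gene-level abundance TSV (gene, value), header required."""
    df = _read_two_column(path, "value")
    genes = df["gene"].astype(str)
    if uppercase:
        genes = genes.str.upper()
    return AbundanceTable(
        tuple(genes), tuple(df["value"].astype(float)), source_label or str(path)
    )


def read_half_life_table(
    path: str | Path, cap_h: float = HALF_LIFE_CAP_H, uppercase: bool = True
) -> dict[str, float]:
    """Protein half-life TSV (gene, hours); values above the cap are clamped
    on load (the upstream turnover dataset reports 100 h as its ceiling) and
    the number of clamped entries is logged."""
    df = _read_two_column(path, "hours")
    genes = df["gene"].astype(str)
    if uppercase:
        genes = genes.str.upper()
    hours = df["hours"].astype(float)
    clamped = int((hours > cap_h).sum())
    if clamped:
        logger.info("half-life table %s: clamped %d value(s) to %.0f h",
                    path, clamped, cap_h)
    return dict(zip(genes, hours.clip(upper=cap_h)))


def read_regions(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Peptide-region TSV: protein_id, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = ["protein_id", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table {path} lacks column(s) {missing}")
    regions: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        regions.setdefault(str(row["protein_id"]), []).append(
            (int(row["start"]), int(row["end"]))
        )
    return regions
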