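"""Stage orchestration: simulate -> map -> census -> quant -> enrich -> conserve.

``run_pipeline`` reads one structured config file, executes the requested
stages, and writes tidy CSV/TSV reports plus a run manifest into the output
directory.  Reports are deterministic under (inputs, seed); the manifest
records the config digest, seed and tool version so every output can be
traced to the invocation that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__, census, conserve, core, enrich, io, quant, simulate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "quantify_observations", "map_peptide_table"]


def _config_digest(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def map_peptide_table(
    peptide_df: pd.DataFrame, proteome: Sequence[core.ProteinRecord]
) -> tuple[pd.DataFrame, list[tuple[core.PeptideMatch, core.ProteinRecord]]]:
    """Map every peptide row to the proteome and fill coordinates/flanks.

    Returns the completed table (one row per match) and the list of
    canonical (match, protein) pairs used for census statistics.  Rows whose
    sequence occurs nowhere are kept with empty coordinates and counted in
    the log; conflicting gene annotations are reported, not fatal.
    """
    by_id = {p.id: p for p in proteome}
    records = io.peptide_records(peptide_df)
    rows = []
    canonical: list[tuple[core.PeptideMatch, core.ProteinRecord]] = []
    n_unmapped = 0
    for rec in records:
        matches = core.map_peptide(rec, proteome)
        if not matches:
            n_unmapped += 1
            rows.append(
                {
                    "sequence": rec.sequence, "n_acetyl": int(rec.n_acetyl),
                    "ox_met": ";".join(map(str, rec.ox_met_positions)),
                    "gene": rec.gene, "protein_id": "", "start": "", "end": "",
                    "upstream": "", "downstream": "",
                    "mass": round(core.monoisotopic_mass(rec), 5),
                }
            )
            continue
        if rec.gene and not any(
            by_id[m.protein_id].gene == rec.gene for m in matches
        ):
            logger.warning(
                "peptide %s annotated gene=%s but matches only %s",
                rec.sequence, rec.gene,
                sorted({by_id[m.protein_id].gene for m in matches}),
            )
        first_canonical = next(m for m in matches if m.canonical)
        canonical.append((first_canonical, by_id[first_canonical.protein_id]))
        for m in matches:
            rows.append(
                {
                    "sequence": rec.sequence, "n_acetyl": int(rec.n_acetyl),
                    "ox_met": ";".join(map(str, rec.ox_met_positions)),
                    "gene": rec.gene, "protein_id": m.protein_id,
                    "start": m.start, "end": m.end,
                    "upstream": m.upstream_flank, "downstream": m.downstream_flank,
                    "mass": round(core.monoisotopic_mass(rec), 5),
                }
            )
    if n_unmapped:
        logger.warning("%d peptide(s) matched nothing in the proteome", n_unmapped)
    return pd.DataFrame(rows), canonical


def quantify_observations(
    observations: Sequence[quant.IntensityObservation],
    designs: Mapping[str, quant.ChannelDesign],
    gene_of: Mapping[tuple[str, str], str] | None = None,
    min_runs: int = 3,
    fold_threshold: float = 2.0,
) -> tuple[list[quant.DifferentialResult], pd.DataFrame]:
    """Charge-state averaging + control normalization + pooled testing.

    Returns the differential results (peptides in >= ``min_runs`` runs) and
    a long per-replicate ratio table (peptide, run, channel, group, ratio)
    for rank plots.  Runs whose design is missing, or peptide/run pairs with
    no detected control channel, are excluded with a warning.
    """
    grouped: dict[tuple[tuple[str, str], str], list] = {}
    for obs in observations:
        if obs.run_id not in designs:
            logger.warning("run %s has no design entry; excluded", obs.run_id)
            continue
        grouped.setdefault((obs.peptide_key, obs.run_id), []).append(obs)

    levels_by_peptide: dict[tuple[str, str], list[quant.RelativeLevelSet]] = {}
    ratio_rows = []
    for (key, run_id), obs_list in sorted(grouped.items()):
        combined = quant.average_charge_states(obs_list)
        design = designs[run_id]
        try:
            levels = quant.relative_levels(combined, design)
        except ValueError as exc:
            logger.warning("%s", exc)
            continue
        levels_by_peptide.setdefault(key, []).append(levels)
        for ch, ratio in levels.ratio_by_channel.items():
            ratio_rows.append(
                {
                    "sequence": key[0], "mod_signature": key[1], "run_id": run_id,
                    "channel": ch, "group": design.group_of[ch].value,
                    "replicate": design.replicate_of[ch], "ratio": ratio,
                }
            )
    results = quant.differential_table(
        levels_by_peptide, designs, gene_of=gene_of,
        min_runs=min_runs, fold_threshold=fold_threshold,
    )
    return results, pd.DataFrame(ratio_rows)


def _differential_frame(results: Sequence[quant.DifferentialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "sequence": r.peptide_key[0], "mod_signature": r.peptide_key[1],
                "gene": r.gene,
                "control_avg": round(r.control_mean, 2),
                "control_sem": round(r.control_sem, 2),
                "n": r.n_control,
                "treated_avg": round(r.treated_mean, 2),
                "treated_sem": round(r.treated_sem, 2),
                "n_treated": r.n_treated,
                "p_value": "" if r.p_value is None else f"{r.p_value:.4g}",
                "tier": r.tier.value,
                "fold_class": r.fold_class.value,
                "bh_q": "" if getattr(r, "bh_q", None) is None else f"{r.bh_q:.4g}",
                "flags": "degenerate" if r.degenerate else (
                    "insufficient" if r.insufficient else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: str | Path | Mapping, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute the configured stages and write reports under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``).  Partial
    failures abort the failing stage with a named-column diagnostic but do
    not erase outputs already written.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    all_stages = ("simulate", "map", "census", "quant", "enrich", "conserve")
    enabled = set(config.get("stages") or all_stages)
    unknown = enabled - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")
    params = dict(config.get("params", {}))
    min_runs = int(params.get("min_runs", 3))
    fold_threshold = float(params.get("fold_threshold", 2.0))
    mass_window = tuple(params.get("mass_window", (900.0, 3000.0)))

    manifest: dict = {
        "tool": "peptidome",
        "version": __version__,
        "seed": seed,
        "config_digest": _config_digest(config),
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "stages": {},
        "outputs": [],
    }

    def _emit(name: str, df: pd.DataFrame, sep: str = ",") -> None:
        path = out / name
        df.to_csv(path, index=False, sep=sep)
        manifest["outputs"].append(name)

    inputs = dict(config.get("inputs", {}))

    # --- simulate ---------------------------------------------------------
    if "simulate" in config and "simulate" in enabled:
        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs["seed"] = seed
        sim = simulate.SimConfig(**sim_kwargs)
        proteome = simulate.make_proteome(sim)
        peptides, truth = simulate.make_peptidome(proteome, sim)
        tables, designs = simulate.make_intensity_tables(peptides, truth, sim)
        io.write_fasta(proteome, out / "proteome.fasta")
        pep_rows = pd.DataFrame(
            {
                "sequence": [p.sequence for p in peptides],
                "n_acetyl": [int(p.n_acetyl) for p in peptides],
                "ox_met": [";".join(map(str, p.ox_met_positions)) for p in peptides],
                "gene": [p.gene for p in peptides],
                "protein_id": "", "start": "", "end": "",
                "upstream": "", "downstream": "",
                "mass": [round(core.monoisotopic_mass(p), 5) for p in peptides],
            }
        )
        io.write_peptide_table(pep_rows, out / "peptides.tsv")
        for run_id, df in tables.items():
            io.write_intensity_table(df, out / f"intensities_{run_id}.tsv")
        simulate.write_ground_truth(truth, out / "ground_truth.json")
        design_yaml = {
            "runs": {
                rid: {
                    ch: {
                        "group": d.group_of[ch].value,
                        "replicate": d.replicate_of[ch],
                    }
                    for ch in d.channels
                }
                for rid, d in designs.items()
            }
        }
        (out / "design.yaml").write_text(yaml.safe_dump(design_yaml, sort_keys=True))
        inputs.setdefault("proteome", str(out / "proteome.fasta"))
        inputs.setdefault("peptides", str(out / "peptides.tsv"))
        inputs.setdefault(
            "intensities",
            [str(out / f"intensities_{rid}.tsv") for rid in sorted(tables)],
        )
        inputs.setdefault("design", str(out / "design.yaml"))
        manifest["stages"]["simulate"] = "ok"

    proteome = None
    canonical: list[tuple[core.PeptideMatch, core.ProteinRecord]] = []
    peptide_df = None

    # --- map --------------------------------------------------------------
    if "proteome" in inputs and "peptides" in inputs and "map" in enabled:
        proteome = io.read_fasta(inputs["proteome"])
        peptide_df = io.read_peptide_table(inputs["peptides"])
        mapped, canonical = map_peptide_table(peptide_df, proteome)
        _emit("peptides_mapped.tsv", mapped, sep="\t")
        manifest["stages"]["map"] = "ok"

    # --- census -----------------------------------------------------------
    if canonical and "census" in enabled:
        peptides = [m.peptide for m, _ in canonical]
        _emit("composition.csv", census.aa_composition(peptides).to_frame())
        _emit("nterm_residues.csv", census.nterm_residue_freq(peptides).to_frame())
        classes = [core.classify_terminal(m, p) for m, p in canonical]
        _emit("terminal_tally.csv", census.terminal_tally(classes).to_frame())
        sites = [core.cleavage_sites(m, p) for m, p in canonical]
        per_site, per_pep = census.cleavage_tally(sites)
        _emit("cleavage_per_site.csv", per_site.to_frame())
        _emit("cleavage_per_peptide.csv", per_pep.to_frame())
        masses = [core.monoisotopic_mass(p) for p in peptides]
        ss = census.size_stats(masses, window=mass_window)
        _emit(
            "size_stats.csv",
            pd.DataFrame(
                [
                    {
                        "mean_mass": round(ss.mean_mass, 2),
                        "median_mass": round(ss.median_mass, 2),
                        "fraction_in_window": round(ss.fraction_in_window, 4),
                        "window_low": ss.window[0], "window_high": ss.window[1],
                        "n": ss.n,
                        "acetyl_fraction": round(census.acetyl_fraction(peptides), 4),
                    }
                ]
            ),
        )
        precursors = sorted(
            {p.id: p for _, p in canonical}.values(), key=lambda p: p.id
        )
        _emit("location_tally.csv",
              census.tally_by_category(precursors, "location").to_frame())
        _emit("function_tally.csv",
              census.tally_by_category(precursors, "function").to_frame())
        manifest["stages"]["census"] = "ok"

    # --- quant ------------------------------------------------------------
    if "intensities" in inputs and "design" in inputs and "quant" in enabled:
        designs = io.read_design(inputs["design"])
        channels = sorted({ch for d in designs.values() for ch in d.channels})
        observations = []
        for path in inputs["intensities"]:
            observations.extend(io.read_intensity_table(path, channels))
        gene_of = None
        if peptide_df is not None and "gene" in peptide_df.columns:
            gene_of = {}
            for _, row in peptide_df.iterrows():
                rec = io.peptide_records(row.to_frame().T)[0]
                gene_of[(rec.sequence, rec.mod_signature)] = rec.gene
        results, ratios = quantify_observations(
            observations, designs, gene_of=gene_of,
            min_runs=min_runs, fold_threshold=fold_threshold,
        )
        _emit("differential.tsv", _differential_frame(results), sep="\t")
        if len(ratios):
            ranked = quant.rank_plot_data(ratios["ratio"])
            rank_df = ratios.sort_values("ratio", kind="stable").reset_index(drop=True)
            rank_df.insert(0, "rank", [r for r, _ in ranked])
            _emit("rank_plot.csv", rank_df)
            treated = ratios.loc[ratios["group"] == "TREATED", "ratio"]
            tally = quant.fold_change_tally(treated, threshold=fold_threshold)
            _emit("fold_change_tally.csv", pd.DataFrame([tally]))
        manifest["stages"]["quant"] = "ok"

    # --- enrich -----------------------------------------------------------
    if canonical and "enrich" in enabled:
        counts: dict[str, int] = {}
        for _, p in canonical:
            counts[p.id] = counts.get(p.id, 0) + 1
        precursors = sorted({p.id: p for _, p in canonical}.values(),
                            key=lambda p: p.id)
        mean_len, median_len, curve = enrich.length_stats(precursors)
        _emit(
            "length_stats.csv",
            pd.DataFrame(
                [
                    {
                        "mean_length": round(mean_len, 1),
                        "median_length": median_len,
                        "n_proteins": len(precursors),
                        "min_proteins_half_peptides": enrich.min_proteins_covering(
                            counts, 0.5
                        ),
                    }
                ]
            ),
        )
        if "abundance" in inputs:
            table = io.read_abundance_table(inputs["abundance"])
            genes = [p.gene.upper() for p in precursors]
            n_bins = int(params.get("n_bins", 10))
            bin_size = int(params.get("bin_size", max(1, len(table.genes) // n_bins)))
            bc = enrich.rank_bin(table, genes, bin_size, n_bins)
            _emit(
                "abundance_bins.csv",
                pd.DataFrame(
                    [
                        {"bin_low_rank": lo, "bin_high_rank": hi, "hits": hits}
                        for (lo, hi), hits in bc.bins
                    ]
                    + [{"bin_low_rank": "", "bin_high_rank": "overflow",
                        "hits": bc.overflow}]
                ),
            )
        if "half_life" in inputs:
            hl = io.read_half_life_table(inputs["half_life"])
            genes = [p.gene.upper() for p in precursors]
            sub, full = enrich.half_life_stats(hl, genes)
            _emit(
                "half_life.csv",
                pd.DataFrame(
                    [
                        {"set": "peptidome", "median_h": sub.median_h,
                         "frac_le_3h": sub.frac_le_3h, "frac_ge_100h": sub.frac_ge_cap,
                         "n": sub.n, "n_missing": sub.n_missing},
                        {"set": "all", "median_h": full.median_h,
                         "frac_le_3h": full.frac_le_3h, "frac_ge_100h": full.frac_ge_cap,
                         "n": full.n, "n_missing": 0},
                    ]
                ),
            )
        manifest["stages"]["enrich"] = "ok"

    # --- conserve ---------------------------------------------------------
    if "orthologs" in inputs and "regions" in inputs and "conserve" in enabled:
        regions_by_protein = io.read_regions(inputs["regions"])
        scheme = conserve.SubstitutionScheme.blosum62()
        reports = []
        for path in inputs["orthologs"]:
            seqs = [(p.id, p.sequence) for p in io.read_fasta(path)]
            reference_id = seqs[0][0]  # first record is the reference
            aln = conserve.progressive_align(seqs, scheme)
            regs = regions_by_protein.get(reference_id, [])
            rep = conserve.region_identity(
                aln, reference_id, regs, scheme_label=scheme.label
            )
            reports.append(
                {
                    "set_id": rep.set_id,
                    "peptide_aa": rep.peptide_region_length,
                    "protein_aa": rep.protein_length,
                    "identity_within_peptides_pct": round(
                        rep.identity_within_peptides, 1
                    ),
                    "identity_whole_pct": round(rep.identity_whole, 1),
                    "scheme": rep.scheme_label,
                }
            )
        _emit("conservation.csv", pd.DataFrame(reports))
        manifest["stages"]["conserve"] = "ok"

    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
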