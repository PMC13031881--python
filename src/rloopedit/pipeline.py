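"""Stage orchestration: simulate -> spectra -> features -> integrate ->
diffpeaks -> dsb -> report.

Each stage reads only fixture files and earlier stage outputs, writes into
its own subdirectory of the run directory and returns a machine-readable
summary; ``run_pipeline`` chains them and writes a JSON run report with
parameter echo, per-stage timings and input checksums.  All randomness
flows from the configured seeds, so a run is fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import clusters_to_tsv, detect_clusters, intermutation_distance
from .config import PipelineConfig
from .diffpeaks import classify_induced, test_differential, test_interaction
from .dsb import classify_dsbs, dependence_ratio_by_class
from .genome import read_fasta
from .integration import (
    classify_proximity,
    replication_quartile_rates,
    state_enrichment,
    strand_concordance,
)
from .intervals import BED_COLUMNS, PeakSet, points_to_peakset
from .mutations import read_vcf
from .seqfeatures import gc_skew_track, g4hunter_scan, profile_around
from .spectra import build_96_spectrum, classify_all, spectrum_to_tsv
from .synthetic import read_counts_tsv, write_fixture_bundle
from .tracks import SignalTrack

STAGES = ["simulate", "spectra", "features", "integrate", "diffpeaks", "dsb"]


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _fixture_paths(fixture_dir: Path) -> dict[str, Path]:
    return {
        "genome": fixture_dir / "genome.fa",
        "mutations": fixture_dir / "mutations.vcf",
        "rloops": fixture_dir / "rloops.bed",
        "a3b": fixture_dir / "a3b_peaks.bed",
        "dsb": fixture_dir / "dsb_peaks.bed",
        "spi_counts": fixture_dir / "spi_counts.tsv",
        "dsb_counts": fixture_dir / "dsb_counts_full.tsv",
        "timing": fixture_dir / "replication_timing.bedGraph",
        "states": fixture_dir / "chromatin_states.bed",
        "truth": fixture_dir / "truth.tsv",
    }


def _design_from_columns(columns) -> tuple[pd.Series, pd.Series]:
    """Recover the (condition, genotype) design from DSB sample names."""
    cond = pd.Series({c: c.split("_")[0] for c in columns})
    geno = pd.Series({c: c.split("_")[1] for c in columns})
    return cond, geno


def stage_simulate(config: PipelineConfig, run_dir: Path) -> dict:
    bundle = write_fixture_bundle(config.synthetic, run_dir / "fixture")
    return {"fixture_dir": str(bundle.directory)}


def stage_spectra(config: PipelineConfig, run_dir: Path) -> dict:
    fx = _fixture_paths(run_dir / "fixture")
    out = run_dir / "spectra"
    out.mkdir(exist_ok=True)
    genome = read_fasta(fx["genome"])
    mutations = read_vcf(fx["mutations"])
    spectrum, summary = build_96_spectrum(mutations, genome)
    spectrum_to_tsv(spectrum, out / "spectrum_96.tsv")
    summary.rename_axis("class").to_frame("count").to_csv(
        out / "class_summary.tsv", sep="\t"
    )
    imd = intermutation_distance(mutations)
    pd.DataFrame({"imd": imd}).to_csv(out / "imd.tsv", sep="\t", index=False)
    callable_regions = PeakSet(
        pd.DataFrame(
            [(c, 0, len(s), ".", 0.0, ".") for c, s in genome.items()],
            columns=BED_COLUMNS,
        )
    )
    clusters, cluster_summary = detect_clusters(
        mutations,
        callable_regions,
        d_max=config.d_cluster,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    clusters_to_tsv(clusters, out / "clusters.tsv")
    cluster_summary.to_csv(out / "cluster_summary.tsv", sep="\t", index=False)
    tcw_fraction = float(
        classify_all(mutations[mutations["ref"].isin(["C", "G"])], genome)["is_tcw"].mean()
    )
    return {
        "n_mutations": int(len(mutations)),
        "n_omikli": int(cluster_summary["omikli"].sum()),
        "n_kataegis": int(cluster_summary["kataegis"].sum()),
        "tcw_fraction_of_c_mutations": tcw_fraction,
    }


def stage_features(config: PipelineConfig, run_dir: Path) -> dict:
    fx = _fixture_paths(run_dir / "fixture")
    out = run_dir / "features"
    out.mkdir(exist_ok=True)
    genome = read_fasta(fx["genome"])
    rloops = PeakSet.read_bed(fx["rloops"])
    skew_plus, skew_minus = gc_skew_track(genome, window=config.gcskew_window)
    skew_plus.write_bedgraph(out / "gc_skew_plus.bedGraph")
    skew_minus.write_bedgraph(out / "gc_skew_minus.bedGraph")
    g4, g4_density = g4hunter_scan(
        genome,
        window=config.g4_window,
        threshold=config.g4_threshold,
        density_bin=config.g4_density_bin,
    )
    g4.write_bed(out / "g4_intervals.bed")
    g4_density.write_bedgraph(out / "g4_density.bedGraph")
    skew_profile = profile_around(
        rloops,
        skew_plus,
        flank=config.profile_flank,
        strand_aware=True,
        antisymmetric=True,
    )
    skew_profile.to_csv(out / "gc_skew_profile.tsv", sep="\t", index=False)
    flank_d = (config.profile_flank // config.g4_density_bin) * config.g4_density_bin
    g4_profile = profile_around(rloops, g4_density, flank=flank_d, strand_aware=True)
    g4_profile.to_csv(out / "g4_density_profile.tsv", sep="\t", index=False)
    inner = skew_profile[np.abs(skew_profile["rel_pos"]) < 200]
    return {
        "n_g4_intervals": int(len(g4)),
        "rloop_center_skew": float(inner["mean"].mean()),
    }


def stage_integrate(config: PipelineConfig, run_dir: Path) -> dict:
    fx = _fixture_paths(run_dir / "fixture")
    out = run_dir / "integrate"
    out.mkdir(exist_ok=True)
    genome = read_fasta(fx["genome"])
    lengths = {c: len(s) for c, s in genome.items()}
    rloops = PeakSet.read_bed(fx["rloops"])
    a3b = PeakSet.read_bed(fx["a3b"])
    mutations = read_vcf(fx["mutations"])
    classified = classify_all(mutations, genome)

    labels, fractions = classify_proximity(a3b, rloops, d=config.d_proximity)
    fractions.rename_axis("label").to_frame("fraction").to_csv(
        out / "a3b_rloop_proximity.tsv", sep="\t"
    )
    conc = strand_concordance(
        classified, rloops, rloop_strand_means=config.rloop_strand_means
    )
    with open(out / "strand_concordance.json", "w") as fh:
        json.dump(
            {
                "n_in_rloop": conc.n_in_rloop,
                "n_concordant": conc.n_concordant,
                "n_excluded_ambiguous": conc.n_excluded_ambiguous,
                "fraction": conc.fraction,
                "ci_low": conc.ci_low,
                "ci_high": conc.ci_high,
                "chi2": conc.chi2,
                "p_value": conc.p_value,
            },
            fh,
            indent=2,
        )

    states = PeakSet.read_bed(fx["states"])
    snv_targets = points_to_peakset(
        classified["contig"].tolist(),
        classified["position"].to_numpy(),
        flank=0,
        contig_lengths=lengths,
    )
    enrich = state_enrichment(
        snv_targets,
        states,
        genome_bases=sum(lengths.values()),
        flank=config.snv_flank,
        contig_lengths=lengths,
    )
    enrich.to_csv(out / "state_enrichment.tsv", sep="\t", index=False)

    timing = SignalTrack.read_bedgraph(
        fx["timing"], config.synthetic.timing_bin, lengths
    )
    rates = replication_quartile_rates(mutations, timing)
    rates.to_csv(out / "replication_quartile_rates.tsv", sep="\t", index=False)
    return {
        "a3b_rloop_overlapping_fraction": float(fractions["overlapping"]),
        "a3b_rloop_proximal_fraction": float(fractions["proximal"]),
        "concordance": conc.fraction,
    }


def stage_diffpeaks(config: PipelineConfig, run_dir: Path) -> dict:
    fx = _fixture_paths(run_dir / "fixture")
    out = run_dir / "diffpeaks"
    out.mkdir(exist_ok=True)
    counts = read_counts_tsv(fx["spi_counts"])
    condition = pd.Series(
        ["control" if c.startswith("ctrl") else "treated" for c in counts.columns],
        index=counts.columns,
    )
    results = test_differential(counts, condition)
    flagged = classify_induced(
        results, fdr=config.fdr, fc=config.fc, top_fraction=config.top_fraction
    )
    flagged.rename_axis("feature").to_csv(out / "spi_differential.tsv", sep="\t")
    return {
        "n_features": int(len(flagged)),
        "n_induced": int(flagged["induced"].sum()),
    }


def stage_dsb(config: PipelineConfig, run_dir: Path) -> dict:
    fx = _fixture_paths(run_dir / "fixture")
    out = run_dir / "dsb"
    out.mkdir(exist_ok=True)
    dsb = PeakSet.read_bed(fx["dsb"])
    a3b = PeakSet.read_bed(fx["a3b"])
    rloops = PeakSet.read_bed(fx["rloops"])
    counts = read_counts_tsv(fx["dsb_counts"])
    condition, genotype = _design_from_columns(counts.columns)

    nt_cols = [c for c in counts.columns if genotype[c] == "NT"]
    e2_cols = [c for c in counts.columns if condition[c] == "E2"]
    e2_res = test_differential(counts[nt_cols], condition[nt_cols])
    kd_res = test_differential(counts[e2_cols], genotype[e2_cols])
    table = classify_dsbs(
        e2_res, kd_res, dsb, a3b, rloops, d=config.d_proximity,
        fdr=config.fdr, fc=config.fc,
    )
    table.table.rename_axis("feature").to_csv(out / "dsb_classes.tsv", sep="\t")
    table.fractions.to_csv(out / "dsb_class_fractions.tsv", sep="\t", index=False)

    summary, test = dependence_ratio_by_class(
        counts[e2_cols], genotype[e2_cols], table.table
    )
    summary.to_csv(out / "dependence_by_class.tsv", sep="\t", index=False)
    interaction = test_interaction(counts, condition, genotype)
    interaction.rename_axis("feature").to_csv(out / "interaction.tsv", sep="\t")
    dep_row = summary[summary["feature_class"] == "A3B_and_Rloop"]
    other = summary[summary["feature_class"] == "neither"]
    report = {
        "n_dsb": int(len(dsb)),
        "n_e2_induced": int(table.table["E2_induced"].sum()),
        "n_a3b_modified": int(table.table["A3B_modified"].sum()),
        "class_association_chi2": table.chi2,
        "class_association_p": table.p_value,
        "dependent_class_mean_log2_ratio": (
            float(dep_row["mean_log2_ratio"].iloc[0]) if len(dep_row) else None
        ),
        "neither_class_mean_log2_ratio": (
            float(other["mean_log2_ratio"].iloc[0]) if len(other) else None
        ),
        "welch_p": test.get("welch_p"),
    }
    with open(out / "dsb_summary.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "spectra": stage_spectra,
    "features": stage_features,
    "integrate": stage_integrate,
    "diffpeaks": stage_diffpeaks,
    "dsb": stage_dsb,
}


def run_stage(name: str, config: PipelineConfig, run_dir: Path) -> dict:
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    return _STAGE_FUNCS[name](config, Path(run_dir))


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; returns the run report."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "resolved_config.yaml")
    wanted = STAGES if stages is None else [s for s in STAGES if s in stages]
    report: dict = {"version": __version__, "stages": {}, "checksums": {}}
    for name in wanted:
        t0 = time.perf_counter()
        summary = run_stage(name, config, run_dir)
        report["stages"][name] = {
            "summary": summary,
            "seconds": round(time.perf_counter() - t0, 3),
        }
    fixture = run_dir / "fixture"
    if fixture.is_dir():
        for p in sorted(fixture.iterdir()):
            if p.suffix != ".fai":
                report["checksums"][p.name] = _checksum(p)
    with open(run_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
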