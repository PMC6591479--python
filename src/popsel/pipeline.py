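"""End-to-end pipeline: simulate/ingest -> QC -> relatedness -> structure -> scan.

Configuration is a flat key=value file whose defaults equal the source
study's printed thresholds (missingness 0.10, MAF 0.01, HWE 1e-4, pruning
50/5/0.5, inbreeding 0.0156, kinship 0.0084, EHH cutoff 0.05, XP-EHH top
fraction 0.001, empirical p cutoff 0.01, Tajima windows 100000/10000).
Every run writes the resolved configuration and a manifest with SHA-256
checksums beside its outputs; re-running with the same config and seed
reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, relatedness, scan_caller, selection_stats, structure
from .synthetic_data import (PopAlleleCounts, SimSpec, SweepSpec,
                             simulate_structured_genotypes,
                             simulate_sweep_cohort)

log = logging.getLogger("popsel")


@dataclass
class PipelineConfig:
    """All pipeline thresholds; defaults are the study's printed values."""

    out_dir: str = "popsel_out"
    seed: int = 0
    # input: either a VCF (+ sample->population TSV) or a simulation
    vcf: str | None = None
    populations_tsv: str | None = None
    simulate: str | None = None          # "structured" or "sweep"
    n_pops: int = 2
    samples_per_pop: int = 100
    n_variants: int = 5000
    fst_target: float = 0.05
    chrom_length_bp: int = 5_000_000
    recomb_rate: float = 1e-8
    sweep_pop: str = "sweep"
    sweep_s: float = 0.05
    sweep_pos: int = 2_500_000
    sweep_generations: int = 200
    sweep_start_freq: float = 0.01
    sweep_final_freq_min: float = 0.9
    # QC
    max_missing_sample: float = 0.10
    max_missing_snp: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-4
    # pruning
    prune_window_snps: int = 50
    prune_step: int = 5
    prune_r2_max: float = 0.5
    # relatedness
    kin_thresh: float = 0.0084
    f_thresh: float = 0.0156
    # structure
    n_components: int = 10
    f3_outgroup: str | None = None
    f3_block_size: int = 500
    # scan
    scan_pairs: tuple = ()               # (("popA","popB"), ...)
    ehh_cutoff: float = 0.05
    max_extension_bp: int = 1_000_000
    max_gap_bp: int = 200_000
    top_fraction: float = 0.001
    fst_p_max: float = 0.01
    tajima_p_max: float = 0.01
    tajima_window: int = 100_000
    tajima_step: int = 10_000
    min_outlier_snps: int = 2

    def to_file(self, path) -> None:
        with open(path, "w") as out:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if f.name == "scan_pairs":
                    v = ";".join(",".join(p) for p in v)
                out.write(f"{f.name} = {'' if v is None else v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if raw == "":
                kwargs[f.name] = None if f.name in (
                    "vcf", "populations_tsv", "simulate", "f3_outgroup") else f.default
                continue
            if f.name == "scan_pairs":
                kwargs[f.name] = tuple(tuple(p.split(","))
                                       for p in raw.split(";") if p)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(out_dir / "pipeline.log", mode="w")):
        h.setFormatter(fmt)
        log.addHandler(h)


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages in fixed order; returns the manifest.

    Stage order: input/simulation, QC, relatedness screen, LD pruning,
    PCA (+ per-component ANOVA across population labels), optional
    outgroup f3, then per-pair selection scans (F_ST, XP-EHH when phased
    haplotypes exist, Tajima's D) with candidate-region calling and
    cross-comparison overlap.  Each stage logs its input/output sizes;
    failures abort with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {}
    config.to_file(out / "resolved_config.txt")
    manifest["resolved_config.txt"] = hashlib.sha256(
        (out / "resolved_config.txt").read_bytes()).hexdigest()

    # ---- stage: input --------------------------------------------------
    hm = None
    if config.simulate == "sweep":
        spec = SimSpec(n_pops=2, samples_per_pop=config.samples_per_pop,
                       n_variants=config.n_variants, fst_target=0.0,
                       seed=config.seed,
                       chrom_length_bp=config.chrom_length_bp,
                       recomb_rate=config.recomb_rate)
        sweep = SweepSpec(target_pop=config.sweep_pop, s=config.sweep_s,
                          sweep_pos=config.sweep_pos,
                          start_freq=config.sweep_start_freq,
                          generations=config.sweep_generations,
                          final_freq_min=config.sweep_final_freq_min)
        cohort = simulate_sweep_cohort(spec, sweep)
        hm = cohort.haplotypes
        gm = hm.to_genotypes()
        log.info("simulated sweep cohort: %d samples, %d variants, "
                 "sweep at %d (freq %.2f, %d attempts)", gm.n_samples,
                 gm.n_variants, cohort.sweep_pos, cohort.final_freq,
                 cohort.attempts)
    elif config.simulate == "structured":
        spec = SimSpec(n_pops=config.n_pops,
                       samples_per_pop=config.samples_per_pop,
                       n_variants=config.n_variants,
                       fst_target=config.fst_target, seed=config.seed,
                       chrom_length_bp=config.chrom_length_bp,
                       recomb_rate=config.recomb_rate)
        gm, _ = simulate_structured_genotypes(spec)
        log.info("simulated structured cohort: %d samples, %d variants",
                 gm.n_samples, gm.n_variants)
    elif config.vcf:
        gm, hm = genotype_io.read_vcf(config.vcf, config.populations_tsv)
        log.info("read %s: %d samples, %d variants", config.vcf,
                 gm.n_samples, gm.n_variants)
    else:
        raise ValueError("stage input: no vcf and no simulate mode configured")

    pops_present = set(gm.populations)
    for pair in config.scan_pairs:
        for p in pair:
            if p not in pops_present:
                raise ValueError(
                    f"stage input: scan pair population {p!r} absent "
                    f"from cohort (has {sorted(pops_present)})")

    genotype_io.write_vcf(out / "cohort.vcf", gm, hm)
    manifest["cohort.vcf"] = hashlib.sha256(
        (out / "cohort.vcf").read_bytes()).hexdigest()
    genotype_io.write_population_tsv(out / "populations.tsv", gm.samples)
    manifest["populations.tsv"] = hashlib.sha256(
        (out / "populations.tsv").read_bytes()).hexdigest()

    # ---- stage: QC -----------------------------------------------------
    gm_qc, report = genotype_io.qc_filter(
        gm, config.max_missing_sample, config.max_missing_snp,
        config.min_maf, config.hwe_alpha)
    _write(report.to_frame(), out / "qc_report.tsv", manifest)
    log.info("QC: %d -> %d samples, %d -> %d variants", report.n_samples_in,
             report.n_samples_out, report.n_variants_in, report.n_variants_out)
    if hm is not None:
        keep_ids = set(gm_qc.variants["id"])
        vmask = gm.variants["id"].isin(keep_ids).to_numpy()
        smask = hm.samples["sample_id"].isin(
            set(gm_qc.samples["sample_id"])).to_numpy()
        hap_idx = np.flatnonzero(np.repeat(smask, 2))
        hm = genotype_io.HaplotypeMatrix(
            hm.alleles[np.ix_(hap_idx, np.flatnonzero(vmask))],
            hm.variants[vmask].reset_index(drop=True),
            hm.samples[smask].reset_index(drop=True))

    # ---- stage: relatedness -------------------------------------------
    kin = relatedness.king_kinship(gm_qc)
    inb = relatedness.inbreeding_f(gm_qc)
    _write(kin.pairs, out / "kinship.tsv", manifest)
    _write(inb.table, out / "inbreeding.tsv", manifest)
    excl = relatedness.flag_related_and_inbred(
        kin, inb, gm_qc, config.kin_thresh, config.f_thresh)
    _write(excl, out / "excluded_samples.tsv", manifest)
    log.info("relatedness: %d samples excluded", len(excl))
    if len(excl):
        keep = ~gm_qc.samples["sample_id"].isin(excl["sample_id"]).to_numpy()
        gm_qc = gm_qc.take_samples(np.flatnonzero(keep))
        if hm is not None:
            keep_full = ~hm.samples["sample_id"].isin(
                excl["sample_id"]).to_numpy()
            hap_idx = np.flatnonzero(np.repeat(keep_full, 2))
            hm = genotype_io.HaplotypeMatrix(
                hm.alleles[hap_idx],
                hm.variants,
                hm.samples[keep_full].reset_index(drop=True))

    # ---- stage: structure ---------------------------------------------
    pruned_idx = genotype_io.ld_prune(gm_qc, config.prune_window_snps,
                                      config.prune_step, config.prune_r2_max)
    log.info("LD pruning: %d -> %d variants", gm_qc.n_variants, pruned_idx.size)
    gm_pruned = gm_qc.take_variants(pruned_idx)
    n_comp = min(config.n_components, gm_pruned.n_samples - 1)
    model = structure.pca_fit(gm_pruned, n_comp)
    _write(model.scores.reset_index(), out / "pca_scores.tsv", manifest)
    _write(pd.DataFrame({"component": model.scores.columns,
                         "explained_variance_ratio":
                         model.explained_variance_ratio}),
           out / "pca_eigenvalues.tsv", manifest)
    if len(set(gm_pruned.populations)) >= 2:
        anova = structure.anova_on_scores(model.scores, gm_pruned.populations)
        _write(anova, out / "pca_anova.tsv", manifest)
        fst_matrix = selection_stats.pairwise_mean_fst(gm_pruned)
        _write(fst_matrix.reset_index(names="population"),
               out / "pairwise_fst.tsv", manifest)

    if config.f3_outgroup:
        counts = PopAlleleCounts.from_genotypes(gm_qc)
        f3 = structure.f3_table(counts, config.f3_outgroup,
                                config.f3_block_size)
        _write(f3, out / "f3.tsv", manifest)

    # ---- stage: selection scans ---------------------------------------
    region_lists: dict[str, list] = {}
    for pa, pb in config.scan_pairs:
        comp = f"{pa}-{pb}"
        fst = selection_stats.wc_fst_per_snp(gm_qc, pa, pb)
        fst_track = fst.table.copy()
        fst_track["empirical_p"] = scan_caller.empirical_p(
            fst_track["theta_clamped"].to_numpy(), direction="high")
        _write(fst_track, out / f"fst_{comp}.tsv", manifest)
        log.info("scan %s: mean F_ST %.4f", comp, fst.mean_fst)
        if hm is None:
            log.info("scan %s: no phased haplotypes, skipping XP-EHH", comp)
            continue
        track = selection_stats.xpehh_scan(
            hm.subset_population(pa), hm.subset_population(pb),
            config.ehh_cutoff, config.max_extension_bp, config.max_gap_bp)
        _write(track.table, out / f"xpehh_{comp}.tsv", manifest)
        outliers = scan_caller.xpehh_outliers(track.table,
                                              config.top_fraction)
        regions = scan_caller.call_composite_regions(
            outliers, fst_track, config.max_gap_bp,
            config.min_outlier_snps, config.fst_p_max, label=comp)
        region_lists[comp] = regions
        _write(scan_caller.regions_to_frame(regions),
               out / f"regions_{comp}.tsv", manifest)
        genotype_io.write_bed(out / f"regions_{comp}.bed", regions)
        manifest[f"regions_{comp}.bed"] = hashlib.sha256(
            (out / f"regions_{comp}.bed").read_bytes()).hexdigest()
        log.info("scan %s: %d composite candidate regions", comp,
                 len(regions))

    if config.scan_pairs and hm is not None:
        for pop in sorted({p for pair in config.scan_pairs for p in pair}):
            windows = selection_stats.tajima_d_windows(
                hm.subset_population(pop), config.tajima_window,
                config.tajima_step)
            _write(windows, out / f"tajima_{pop}.tsv", manifest)
            tregions = scan_caller.call_tajima_regions(
                windows, config.tajima_p_max, label=f"tajima-{pop}")
            _write(scan_caller.regions_to_frame(tregions),
                   out / f"tajima_regions_{pop}.tsv", manifest)
            region_lists[f"tajima-{pop}"] = tregions

    if len(region_lists) >= 2:
        ov = scan_caller.region_overlap(region_lists)
        venn = pd.DataFrame(
            [("+".join(sorted(cell)), cnt)
             for cell, cnt in sorted(ov.venn_cells.items(),
                                     key=lambda kv: sorted(kv[0]))],
            columns=["labels", "n_regions"])
        _write(venn, out / "region_overlap.tsv", manifest)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("wrote %d outputs to %s", len(manifest), out)
    return manifest
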