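"""Config-driven orchestration of the analysis stages.

A run consumes a YAML (or dict) configuration naming the input files and
thresholds, validates the inputs, then executes somatic profiling →
genome instability → clinical associations → survival screen → germline
association, writing every stage output plus a JSON report under the
output directory. Defaults mirror the study parameters: VAF floor 5 %,
3 supporting reads, MSI cut 20 %, MMR-D cut 1.5 indels/Mb, purity 0.70
with 50 % clonality, 10 % gene-frequency floor for the prognostic screen,
alpha 0.05 and a 3-year RFS dichotomization; every value is overridable.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, germline, instability, io, somatic, stats, survival

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]

DEFAULT_THRESHOLDS = {
    "vaf_min": 0.05,
    "alt_reads_min": 3,
    "msi_fraction": 0.20,
    "mmrd_density": 1.5,
    "purity": 0.70,
    "clonality": 0.50,
    "min_gene_freq": 0.10,
    "germline_min_gene_freq": 0.05,
    "alpha": 0.05,
    "rfs_cut_years": 3.0,
    "n_perm": 10_000,
}


@dataclass
class RunConfig:
    clinical: str
    somatic_maf: str
    output_dir: str
    seg: str | None = None
    genotypes: str | None = None
    genotype_annotations: str | None = None
    reference_fasta: str | None = None
    indel_vcf: str | None = None
    panel_size_mb: float = 2.1
    seed: int = 0
    strata: tuple[str, ...] = ("all", "untreated", "treated")
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def validate_inputs(config: RunConfig, strict: bool = False) -> list[str]:
    """Schema and cross-file consistency checks; returns a list of problems."""
    problems: list[str] = []
    for name in ("clinical", "somatic_maf", "seg", "genotypes",
                 "genotype_annotations", "reference_fasta", "indel_vcf"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"missing input file: {name} = {p}")
    if any(p.startswith("missing input file: clinical") or
           p.startswith("missing input file: somatic_maf") for p in problems):
        if strict:
            raise FileNotFoundError("; ".join(problems))
        return problems

    clinical = io.read_tsv(config.clinical)
    for col in ("patient_id", "stage", "rfs_months", "rfs_event", "os_months", "os_event"):
        if col not in clinical.columns:
            problems.append(f"clinical table lacks column {col!r}")
    variants = io.read_maf(config.somatic_maf)
    for col in ("sample_id", "gene", "vaf", "alt_reads", "filter_status"):
        if col not in variants.columns:
            problems.append(f"somatic table lacks column {col!r}")
    if "vaf" in variants.columns and len(variants):
        vaf = pd.to_numeric(variants["vaf"], errors="coerce")
        if vaf.max() > 1.0:
            problems.append("vaf column looks like percentages (values > 1)")
    if "patient_id" in clinical.columns and "sample_id" in variants.columns:
        orphans = sorted(set(variants["sample_id"]) - set(clinical["patient_id"]))
        if orphans:
            problems.append(f"variant samples absent from clinical: {orphans[:5]}")
    if strict and problems:
        raise ValueError("; ".join(problems))
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute every applicable stage; write outputs and a JSON report."""
    t0 = time.time()
    problems = validate_inputs(config, strict=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {"crcpanel_version": __version__, "config": {
        "panel_size_mb": config.panel_size_mb, "seed": config.seed,
        "thresholds": th}, "stages": {}}

    clinical = io.read_tsv(config.clinical)
    patients = clinical["patient_id"].tolist()

    # --- somatic profile ---
    variants = io.read_maf(config.somatic_maf)
    filtered, rejections = somatic.filter_somatic(
        variants, th["vaf_min"], th["alt_reads_min"], return_rejections=True)
    io.write_maf(filtered, out / "somatic_filtered.tsv")
    carrier = somatic.carrier_matrix(filtered, patients)
    carrier.to_csv(out / "carrier_matrix.tsv", sep="\t")
    counts = somatic.sample_variant_counts(filtered, patients)
    tmb = somatic.compute_tmb(filtered, config.panel_size_mb, patients)
    report["stages"]["somatic"] = {
        "n_input": int(len(variants)), "n_filtered": int(len(filtered)),
        "rejections": rejections,
        "median_variants_per_sample": counts["median_total"],
        "median_tmb": float(np.median(tmb)),
    }

    # --- genome instability ---
    if config.seg is not None:
        seg = io.read_seg(config.seg)
        thresholds = instability.derive_cnv_thresholds(th["purity"], th["clonality"])
        neutral_ref = np.concatenate([
            np.asarray(b, dtype=float) for b in seg["bin_log2"]])
        neutral_ref = neutral_ref[np.abs(neutral_ref) < 0.1]
        if neutral_ref.size < 2:
            neutral_ref = np.zeros(20)
        called = instability.filter_cnv_segments(seg, thresholds, neutral_ref)
        io.write_seg(called.assign(bin_log2=called["bin_log2"]), out / "cnv_called.tsv")
        report["stages"]["cnv"] = {
            "thresholds": thresholds.rounded(), **instability.summarize_cnv(called)}
    if config.reference_fasta is not None and config.indel_vcf is not None:
        seqs = io.read_fasta(config.reference_fasta)
        regions = [r for name, s in seqs.items()
                   for r in instability.find_homopolymers(s, chrom=name)]
        indels = io.read_vcf(config.indel_vcf)
        density = instability.homopolymer_indel_density(
            indels["pos"], regions, config.panel_size_mb)
        report["stages"]["mmrd"] = {
            "n_homopolymer_regions": len(regions),
            "indel_density_per_mb": density,
            "mmrd": instability.classify_mmrd(density, th["mmrd_density"]),
        }

    # --- clinical associations ---
    assoc_rows = []
    stage_map = {"I": "I/II", "II": "I/II", "III": "III/IV", "IV": "III/IV"}
    clin_idx = clinical.set_index("patient_id")
    for gene in carrier.columns:
        flags = (carrier[gene] > 0).reindex(clin_idx.index)
        if flags.sum() in (0, len(flags)):
            continue
        table = stats.build_contingency(
            clin_idx.reset_index(), flags.reset_index(drop=True), "stage", stage_map)
        p = stats.fisher_exact_2x2(table)
        assoc_rows.append(stats.TestResult(
            "fisher_2x2", f"{gene} x stage I/II vs III/IV", float("nan"), p, table.n))
    stats.adjust_family(assoc_rows)
    assoc = pd.DataFrame([{
        "test": r.test_name, "grouping": r.grouping, "p_crude": r.p_crude,
        "p_adj": r.p_adj, "n": r.n} for r in assoc_rows])
    io.write_tsv(assoc, out / "clinical_assoc.tsv")
    report["stages"]["clinical_assoc"] = {
        "n_tests": len(assoc_rows),
        "n_significant_adj": int((assoc["p_adj"] < th["alpha"]).sum()) if len(assoc) else 0,
    }

    # --- survival screen ---
    endpoints = survival.build_endpoints(clinical)
    screen = survival.prognostic_screen(
        carrier, endpoints, clinical, min_gene_freq=th["min_gene_freq"],
        alpha=th["alpha"], strata=tuple(config.strata))
    io.write_tsv(screen["single_gene"], out / "survival_single_gene.tsv")
    io.write_tsv(screen["gene_sets"], out / "survival_gene_sets.tsv")
    report["stages"]["survival"] = {
        "family_size": screen["family_size"],
        "sets": {k: v for k, v in screen["sets"].items()},
    }

    # --- germline association ---
    if config.genotypes is not None:
        genotypes = io.read_tsv(config.genotypes, index_col=0)
        pheno = germline.rfs_dichotomize(endpoints, th["rfs_cut_years"])
        maxt = germline.maxt_permutation(
            genotypes, pheno, n_perm=th["n_perm"], seed=config.seed)
        io.write_tsv(maxt, out / "germline_assoc.tsv", index=True)
        entry = {
            "n_variants": int(len(maxt)),
            "n_cases": int((pheno == 1).sum()), "n_controls": int((pheno == 0).sum()),
            "min_p_maxt": float(maxt["p_maxt"].min()),
        }
        if config.genotype_annotations is not None:
            ann = io.read_tsv(config.genotype_annotations, index_col=0)
            short = germline.prioritize_germline(
                ann, genotypes, th["germline_min_gene_freq"])
            entry["n_shortlisted_genes"] = int(len(short["shortlisted_genes"]))
            manhattan = germline.manhattan_table(ann, maxt)
            io.write_tsv(manhattan, out / "germline_manhattan.tsv")
        report["stages"]["germline"] = entry

    report["validation_problems"] = problems
    report["wall_time_s"] = round(time.time() - t0, 2)
    io.write_json(report, out / "report.json")
    return report
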