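"""Synthetic cohort generator with known ground truth.

Every input of the analysis pipeline can be generated here with planted,
recorded truth: a clinical table with staging, treatment and censored
survival endpoints; somatic variant calls with configurable per-gene
mutation probabilities, planted stage associations (odds ratios) and
planted prognostic gene sets (hazard ratios on overall survival); a
reference sequence with homopolymer runs and indels at known positions;
copy-number segments under the clonal-fraction purity model; germline
genotypes in Hardy–Weinberg proportions with planted survival effects;
and a cell-line drug-screen plus tumor-catalog pair for panel design.

Survival times are exponential with proportional planted multipliers;
censoring is uniform over the follow-up window. One global seed fans out
to fixed per-generator child seeds, so adding or re-running one generator
never perturbs another, and a fixed seed gives byte-identical output.

Default cohort structure mirrors a surgical colorectal-cancer series of
83 patients: median age 68 (sd 9.2), 53 % male, stage I/II/III/IV at
12/40/47/1 %, grade G1/G2/G3 at 22/67/11 %, 62 % receiving adjuvant
5-FU-based chemotherapy, median follow-up near four years. Default gene
mutation probabilities follow the frequently mutated colorectal genes
(APC 64 %, TP53 59 %, KRAS 42 %, FAT4 23 %, FBXW7 and PIK3CA 16 %, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .instability import HomopolymerRegion

__all__ = [
    "CohortConfig",
    "generate_clinical",
    "generate_somatic_variants",
    "generate_reference_with_indels",
    "generate_cnv_segments",
    "generate_germline_genotypes",
    "generate_drug_screen_db",
]

# child-seed offsets: one global seed fans out deterministically
_SEED_CARRIERS = 11
_SEED_CLINICAL = 23
_SEED_SOMATIC = 37
_SEED_REFERENCE = 53
_SEED_CNV = 67
_SEED_GERMLINE = 79
_SEED_SCREEN = 97
_SEED_PLANTED_GT = 113

DEFAULT_GENE_FREQUENCIES = {
    "APC": 0.64, "TP53": 0.59, "KRAS": 0.42, "FAT4": 0.23, "FBXW7": 0.16,
    "PIK3CA": 0.16, "ABCA13": 0.18, "ANK2": 0.17, "COL7A1": 0.15,
    "NAV3": 0.16, "UNC80": 0.14, "FLG": 0.18, "GLI3": 0.13, "COL6A3": 0.15,
    "LRP1B": 0.19, "RYR1": 0.14, "RYR3": 0.13, "TCHH": 0.12, "TENM4": 0.12,
    "SACS": 0.12, "KMT2D": 0.13, "SYNE1": 0.20, "OBSCN": 0.17, "MYC": 0.06,
}

_CLASS_MIX = {
    "missense": 0.55, "frameshift_deletion": 0.12, "nonsense": 0.12,
    "frameshift_insertion": 0.05, "splice_site": 0.05, "inframe_deletion": 0.04,
    "inframe_insertion": 0.03, "tss": 0.01, "synonymous": 0.03,
}
_APC_CLASS_MIX = {
    "frameshift_deletion": 0.35, "frameshift_insertion": 0.10, "nonsense": 0.25,
    "missense": 0.25, "splice_site": 0.05,
}
# KRAS hotspot alleles and their share among carriers
_KRAS_ALLELES = {
    "p.G12D": 0.33, "p.G12V": 0.15, "p.G12C": 0.07, "p.G13D": 0.17,
    "p.Q61H": 0.15, "p.A146T": 0.13,
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 83
    seed: int = 0
    stage_distribution: dict = field(default_factory=lambda: {
        "I": 0.12, "II": 0.40, "III": 0.47, "IV": 0.01})
    grade_distribution: dict = field(default_factory=lambda: {
        "G1": 0.22, "G2": 0.67, "G3": 0.11})
    gx_fraction: float = 0.01
    treated_fraction: float = 0.62
    gene_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQUENCIES))
    planted_stage_genes: dict = field(default_factory=lambda: {
        "APC": 3.0, "TP53": 3.0, "KRAS": 2.5})
    planted_prognostic_sets: dict = field(default_factory=lambda: {
        "os5": {"genes": ["ABCA13", "ANK2", "COL7A1", "NAV3", "UNC80"], "hr": 3.0}})
    planted_germline_effects: dict = field(default_factory=dict)
    n_germline_variants: int = 40
    censoring_rate: float = 0.35
    follow_up_months: float = 120.0
    panel_size_mb: float = 2.1
    subthreshold_fraction: float = 0.10
    # baseline monthly hazards (stage II, non-carrier)
    death_hazard: float = math.log(2) / 80.0
    recurrence_hazard: float = math.log(2) / 100.0
    stage_death_multiplier: dict = field(default_factory=lambda: {
        "I": 0.6, "II": 1.0, "III": 1.7, "IV": 5.0})
    stage_recurrence_multiplier: dict = field(default_factory=lambda: {
        "I": 0.5, "II": 1.0, "III": 2.0, "IV": 5.0})

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name, dist in (("stage_distribution", self.stage_distribution),
                           ("grade_distribution", self.grade_distribution)):
            vals = np.array(list(dist.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be proportions summing to 1")
        for p in (self.treated_fraction, self.censoring_rate, self.subthreshold_fraction):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        unknown = set(self.planted_stage_genes) - set(self.gene_frequencies)
        if unknown:
            raise ValueError(f"planted stage genes not in gene_frequencies: {sorted(unknown)}")
        for name, spec in self.planted_prognostic_sets.items():
            if spec["hr"] <= 0:
                raise ValueError(f"hazard ratio of set {name!r} must be positive")
            unknown = set(spec["genes"]) - set(self.gene_frequencies)
            if unknown:
                raise ValueError(f"planted set {name!r} genes not in gene_frequencies: {sorted(unknown)}")


def _rng(config: CohortConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, offset))


def _base_rate_for_marginal(p_g: float, odds_ratio: float, w_advanced: float) -> float:
    """Stage-I/II carrier probability so the cohort marginal equals p_g."""
    if odds_ratio == 1.0 or p_g in (0.0, 1.0):
        return p_g

    def marginal(p0: float) -> float:
        p1 = odds_ratio * p0 / (1 - p0 + odds_ratio * p0)
        return (1 - w_advanced) * p0 + w_advanced * p1 - p_g

    return brentq(marginal, 0.0, 1.0, xtol=1e-12)


def _draw_stages(config: CohortConfig) -> np.ndarray:
    rng = _rng(config, _SEED_CLINICAL)
    stages = list(config.stage_distribution)
    probs = np.array([config.stage_distribution[s] for s in stages])
    return rng.choice(stages, size=config.n_patients, p=probs)


def _draw_carriers(config: CohortConfig, stages: np.ndarray) -> pd.DataFrame:
    """Per-patient carrier indicators for every configured gene.

    Planted stage genes get their odds ratio for stage III/IV realized while
    keeping the configured marginal frequency.
    """
    rng = _rng(config, _SEED_CARRIERS)
    advanced = np.isin(stages, ["III", "IV"])
    w_adv = config.stage_distribution.get("III", 0) + config.stage_distribution.get("IV", 0)
    genes = sorted(config.gene_frequencies)
    out = {}
    for g in genes:
        p_g = config.gene_frequencies[g]
        orr = config.planted_stage_genes.get(g, 1.0)
        p0 = _base_rate_for_marginal(p_g, orr, w_adv)
        p1 = orr * p0 / (1 - p0 + orr * p0) if p_g not in (0, 1) else p_g
        p = np.where(advanced, p1, p0)
        out[g] = rng.random(config.n_patients) < p
    ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    return pd.DataFrame(out, index=ids)


def _draw_planted_genotypes(config: CohortConfig) -> pd.DataFrame:
    """Genotypes (0/1/2) for planted germline variants, Hardy–Weinberg."""
    rng = _rng(config, _SEED_PLANTED_GT)
    ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    rows = {}
    for vid in sorted(config.planted_germline_effects):
        maf = config.planted_germline_effects[vid]["maf"]
        if not 0 <= maf <= 1:
            raise ValueError(f"allele frequency of {vid!r} outside [0,1]")
        rows[vid] = rng.binomial(2, maf, size=config.n_patients)
    return pd.DataFrame(rows, index=ids).T


def generate_clinical(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Clinical table plus truth for the synthetic cohort.

    Survival endpoints: overall survival is time from surgery to death
    from any cause; recurrence-free survival to recurrence, censored at
    death-in-remission or last control. Adjuvant treatment is assigned
    only to stage II–IV patients, at a rate giving the configured overall
    treated fraction. Planted prognostic sets multiply the death hazard of
    set-gene carriers by their hazard ratio; planted germline effects do
    the same per endpoint.
    """
    stages = _draw_stages(config)
    carriers = _draw_carriers(config, stages)
    planted_gt = _draw_planted_genotypes(config)
    rng = _rng(config, _SEED_CLINICAL + 1)
    n = config.n_patients
    ids = list(carriers.index)

    if n == 0:
        cols = ["patient_id", "age", "sex", "stage", "grade", "pT", "pN", "pM",
                "sidedness", "resection", "regimen", "response",
                "rfs_months", "rfs_event", "os_months", "os_event"]
        return pd.DataFrame(columns=cols), {"patients": {}, "carriers": {},
                                            "hazard_multipliers": {}}

    age = np.clip(np.round(rng.normal(68.0, 9.2, n)), 42, 90).astype(int)
    sex = rng.choice(["M", "F"], size=n, p=[0.53, 0.47])
    grades = list(config.grade_distribution)
    gprobs = np.array([config.grade_distribution[g] for g in grades])
    grade = rng.choice(grades, size=n, p=gprobs)
    gx = rng.random(n) < config.gx_fraction
    grade = np.where(gx, "Gx", grade)
    pT = rng.choice(["pT1", "pT2", "pT3", "pT4"], size=n, p=[0.04, 0.14, 0.74, 0.08])
    pN = np.where(np.isin(stages, ["I", "II"]), "pN0",
                  rng.choice(["pN1", "pN2"], size=n, p=[0.62, 0.38]))
    pM = np.where(stages == "IV", "present", "absent")
    sidedness = rng.choice(["right", "left"], size=n, p=[0.40, 0.60])
    resection = rng.choice(["R0", "R1"], size=n, p=[0.96, 0.04])

    # treatment only for stage II-IV; rate set to hit the overall fraction
    eligible = stages != "I"
    frac_eligible = max(eligible.mean(), 1e-9)
    p_treat = min(config.treated_fraction / frac_eligible, 1.0)
    treated = eligible & (rng.random(n) < p_treat)
    regimen = np.where(treated, rng.choice(["5FU", "FOLFOX"], size=n, p=[0.56, 0.44]), "none")
    response = np.where(treated, rng.choice(["stable", "progression"], size=n, p=[0.87, 0.13]),
                        "not_applicable")

    # hazard multipliers: stage plus planted prognostic sets (on OS)
    death_mult = np.array([config.stage_death_multiplier[s] for s in stages], dtype=float)
    rec_mult = np.array([config.stage_recurrence_multiplier[s] for s in stages], dtype=float)
    for spec in config.planted_prognostic_sets.values():
        in_set = carriers[spec["genes"]].any(axis=1).to_numpy()
        death_mult = death_mult * np.where(in_set, spec["hr"], 1.0)
    for vid, eff in config.planted_germline_effects.items():
        carrier = (planted_gt.loc[vid].to_numpy() >= 1)
        death_mult = death_mult * np.where(carrier, eff.get("hr_os", 1.0), 1.0)
        rec_mult = rec_mult * np.where(carrier, eff.get("hr_rfs", 1.0), 1.0)

    t_death = rng.exponential(1.0 / (config.death_hazard * death_mult))
    t_rec = rng.exponential(1.0 / (config.recurrence_hazard * rec_mult))
    dropout = rng.random(n) < config.censoring_rate
    t_cens = np.where(dropout, rng.uniform(0, config.follow_up_months, n),
                      config.follow_up_months)

    os_months = np.minimum(t_death, t_cens)
    os_event = t_death <= t_cens
    rfs_months = np.minimum(t_rec, os_months)
    rfs_event = t_rec < os_months

    clinical = pd.DataFrame({
        "patient_id": ids, "age": age, "sex": sex, "stage": stages, "grade": grade,
        "pT": pT, "pN": pN, "pM": pM, "sidedness": sidedness, "resection": resection,
        "regimen": regimen, "response": response,
        "rfs_months": np.round(rfs_months, 2), "rfs_event": rfs_event,
        "os_months": np.round(os_months, 2), "os_event": os_event,
    })
    truth = {
        "patients": {pid: {"stage": s, "grade": g, "treated": bool(t)}
                     for pid, s, g, t in zip(ids, stages, grade, treated)},
        "carriers": {pid: sorted(carriers.columns[carriers.loc[pid]].tolist()) for pid in ids},
        "hazard_multipliers": {pid: {"death": float(d), "recurrence": float(r)}
                               for pid, d, r in zip(ids, death_mult, rec_mult)},
    }
    return clinical, truth


def _gene_locus(i: int) -> tuple[str, int]:
    return f"chr{(i % 22) + 1}", 1_000_000 * (i + 1)


def generate_somatic_variants(config: CohortConfig, clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Somatic variant table (MAF-like) consistent with the clinical draw.

    Every carrier patient gets at least one HIGH/MODERATE variant in the
    gene; a configurable fraction of additional sub-threshold variants
    (VAF < 5 %, < 3 reads, or non-PASS — flagged in truth) exercises the
    somatic filter. KRAS carriers receive hotspot protein changes.
    """
    carriers = _draw_carriers(config, _draw_stages(config))
    rng = _rng(config, _SEED_SOMATIC)
    genes = sorted(config.gene_frequencies)
    loci = {g: _gene_locus(i) for i, g in enumerate(genes)}
    bases = np.array(list("ACGT"))

    rows = []
    for pid in carriers.index:
        for g in genes:
            if not carriers.loc[pid, g]:
                continue
            n_var = 1 + rng.poisson(0.25)
            for j in range(n_var):
                mix = dict(_APC_CLASS_MIX if g == "APC" else _CLASS_MIX)
                if j == 0:
                    # the first variant realizes carriage: HIGH/MODERATE only
                    mix.pop("synonymous", None)
                classes = list(mix)
                vclass = str(rng.choice(classes, p=np.array(list(mix.values())) / sum(mix.values())))
                protein_change = ""
                if g == "KRAS" and j == 0:
                    alleles = list(_KRAS_ALLELES)
                    protein_change = str(rng.choice(alleles, p=list(_KRAS_ALLELES.values())))
                    vclass = "missense"
                chrom, base_pos = loci[g]
                pos = base_pos + int(rng.integers(0, 50_000))
                ref, alt = _alleles_for_class(vclass, rng, bases)
                vaf = float(np.clip(rng.beta(5, 8), 0.05, 0.95))
                depth = max(int(rng.poisson(150)), 20)
                alt_reads = max(int(round(vaf * depth)), 3)
                rows.append({
                    "sample_id": pid, "gene": g, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "variant_class": vclass,
                    "vaf": round(vaf, 4), "alt_reads": alt_reads,
                    "filter_status": "PASS", "protein_change": protein_change,
                })

    from .somatic import classify_impact

    n_sub = int(round(config.subthreshold_fraction * len(rows)))
    sub_ids = []
    for i in range(n_sub):
        pid = str(rng.choice(carriers.index))
        g = str(rng.choice(genes))
        chrom, base_pos = loci[g]
        mode = str(rng.choice(["low_vaf", "low_reads", "non_pass"]))
        vaf = round(float(rng.uniform(0.005, 0.049)), 4) if mode == "low_vaf" else round(float(rng.uniform(0.05, 0.6)), 4)
        alt_reads = int(rng.integers(0, 3)) if mode == "low_reads" else max(int(round(vaf * 150)), 3)
        filt = "germline_risk" if mode == "non_pass" else "PASS"
        rows.append({
            "sample_id": pid, "gene": g, "chrom": chrom,
            "pos": base_pos + 900_000 + i,
            "ref": "A", "alt": "T", "variant_class": "missense",
            "vaf": vaf, "alt_reads": alt_reads, "filter_status": filt,
            "protein_change": "",
        })
        sub_ids.append(len(rows) - 1)

    variants = pd.DataFrame(rows)
    if len(variants):
        variants["impact"] = variants["variant_class"].map(classify_impact)
        variants = variants[[
            "sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
            "impact", "vaf", "alt_reads", "filter_status", "protein_change",
        ]]
    truth = {
        "carriers": {pid: sorted(carriers.columns[carriers.loc[pid]].tolist())
                     for pid in carriers.index},
        "subthreshold_rows": sub_ids,
    }
    return variants, truth


def _alleles_for_class(vclass: str, rng: np.random.Generator, bases) -> tuple[str, str]:
    a = str(rng.choice(bases))
    b = str(rng.choice([x for x in "ACGT" if x != a]))
    if vclass in ("frameshift_deletion", "inframe_deletion"):
        length = 3 if vclass == "inframe_deletion" else int(rng.choice([1, 2, 4]))
        tail = "".join(rng.choice(bases, size=length))
        return a + tail, a
    if vclass in ("frameshift_insertion", "inframe_insertion"):
        length = 3 if vclass == "inframe_insertion" else int(rng.choice([1, 2, 4]))
        tail = "".join(rng.choice(bases, size=length))
        return a, a + tail
    return a, b


def generate_reference_with_indels(
    length: int,
    homopolymer_spec: list[tuple[int, str, int]],
    indel_spec: dict,
    seed: int = 0,
) -> dict:
    """Reference sequence with planted homopolymer runs and indel calls.

    ``homopolymer_spec`` lists (start, base, run_length) with 0-based
    starts; the background sequence contains no run of five or more, and
    planted runs are made maximal by flanking with different bases.
    ``indel_spec`` gives ``n_inside`` / ``n_outside`` counts (indels whose
    1-based anchored position falls inside / outside planted runs).
    Returns the sequence, truth regions, and an indel table
    (1-based ``pos``, ``ref``, ``alt``, ``in_homopolymer``).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng((seed, _SEED_REFERENCE))
    # background with no run of >= 5 identical bases
    seq = np.empty(length, dtype="<U1")
    bases = "ACGT"
    for i in range(length):
        choices = bases
        if i >= 4 and seq[i - 1] == seq[i - 2] == seq[i - 3] == seq[i - 4]:
            choices = choices.replace(seq[i - 1], "")
        seq[i] = choices[rng.integers(0, len(choices))]

    regions: list[HomopolymerRegion] = []
    for start, base, run_length in homopolymer_spec:
        end = start + run_length
        if run_length > length or start < 0 or end > length:
            raise ValueError("homopolymer does not fit in sequence")
        seq[start:end] = base
        if start > 0 and seq[start - 1] == base:
            seq[start - 1] = "ACGT".replace(base, "")[rng.integers(0, 3)]
        if end < length and seq[end] == base:
            seq[end] = "ACGT".replace(base, "")[rng.integers(0, 3)]
        regions.append(HomopolymerRegion("chr1", start, end, base))

    indel_rows = []
    n_inside = int(indel_spec.get("n_inside", 0))
    n_outside = int(indel_spec.get("n_outside", 0))
    if n_inside and not regions:
        raise ValueError("cannot place inside-run indels without homopolymers")
    inside_positions = np.concatenate(
        [np.arange(r.start, r.end) for r in regions]) if regions else np.array([], dtype=int)
    mask = np.zeros(length, dtype=bool)
    mask[inside_positions] = True
    outside_positions = np.flatnonzero(~mask)
    for n, pool, flag in ((n_inside, inside_positions, True),
                          (n_outside, outside_positions, False)):
        if n > len(pool):
            raise ValueError("more indels requested than available positions")
        chosen = rng.choice(pool, size=n, replace=False)
        for p0 in np.sort(chosen):
            ref_base = seq[p0]
            if rng.random() < 0.5 and p0 + 1 < length:  # deletion of next base
                ref, alt = ref_base + seq[p0 + 1], ref_base
            else:  # insertion after the anchor
                ins = "ACGT"[rng.integers(0, 4)]
                ref, alt = ref_base, ref_base + ins
            indel_rows.append({"chrom": "chr1", "pos": int(p0) + 1, "ref": str(ref),
                               "alt": str(alt), "in_homopolymer": bool(flag)})
    return {
        "sequence": "".join(seq),
        "regions": regions,
        "indels": pd.DataFrame(indel_rows,
                               columns=["chrom", "pos", "ref", "alt", "in_homopolymer"]),
    }


def generate_cnv_segments(
    purity: float,
    clonality: float,
    true_states: list[str],
    bins_per_segment: int | list[int] = 20,
    noise_sd: float = 0.05,
    seed: int = 0,
    baf_sd: float = 0.01,
    sample_id: str = "S1",
    bin_bp: int = 100_000,
) -> tuple[pd.DataFrame, list[str]]:
    """SEG-like table with bins drawn around clonal-fraction expectations.

    With f = purity × clonality, deletion bins center on log2((2 − f)/2)
    and duplication bins on log2((2 + f)/2); neutral on 0. Deletion BAF
    centers on the mono-allelic-loss expectation 1/(2 − f) (mirrored at
    random); duplications are emulated as allele-balanced gains (BAF 0.5).
    """
    if not (0 < purity <= 1) or not (0 < clonality <= 1):
        raise ValueError("purity and clonality must lie in (0, 1]")
    rng = np.random.default_rng((seed, _SEED_CNV))
    f = purity * clonality
    exp_log2 = {"deletion": math.log2((2 - f) / 2),
                "duplication": math.log2((2 + f) / 2), "neutral": 0.0}
    if isinstance(bins_per_segment, int):
        bins_per_segment = [bins_per_segment] * len(true_states)
    rows = []
    start = 0
    for state, nb in zip(true_states, bins_per_segment):
        if nb <= 0:
            raise ValueError("segment with zero bins")
        if state not in exp_log2:
            raise ValueError(f"unknown CNV state {state!r}")
        bins = rng.normal(exp_log2[state], noise_sd, size=nb)
        if state == "deletion":
            center = 1.0 / (2 - f)
            if rng.random() < 0.5:
                center = 1 - center
        else:
            center = 0.5
        baf = float(np.clip(rng.normal(center, baf_sd), 0, 1))
        end = start + nb * bin_bp
        rows.append({"sample_id": sample_id, "chrom": "chr1", "start": start,
                     "end": end, "n_bins": nb, "bin_log2": bins.tolist(),
                     "baf": round(baf, 4)})
        start = end
    return pd.DataFrame(rows), list(true_states)


def generate_germline_genotypes(
    config: CohortConfig,
    clinical: pd.DataFrame,
    planted_variant_effects: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Germline genotype matrix (variants × patients) plus annotations.

    Null variants are drawn in Hardy–Weinberg proportions at random minor
    allele frequencies; planted variants reuse the genotype draw that
    shaped the clinical survival times (their stated hazard multipliers
    are realized there). Annotations carry gene, impact and a
    ClinVar-style flag column.
    """
    if planted_variant_effects is None:
        planted_variant_effects = config.planted_germline_effects
    elif planted_variant_effects != config.planted_germline_effects:
        raise ValueError(
            "planted_variant_effects must match config.planted_germline_effects "
            "(survival times were generated from the config)")
    ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    rng = _rng(config, _SEED_GERMLINE)
    planted = _draw_planted_genotypes(config)

    m = config.n_germline_variants
    mafs = rng.uniform(0.05, 0.4, size=m)
    null_gt = rng.binomial(2, mafs[:, None], size=(m, config.n_patients))
    null_ids = [f"rsN{i + 1:05d}" for i in range(m)]
    genotypes = pd.DataFrame(null_gt, index=null_ids, columns=ids)
    if len(planted):
        genotypes = pd.concat([planted, genotypes])

    genes = [f"GENE{i % 25:02d}" for i in range(len(genotypes))]
    impacts = rng.choice(["HIGH", "MODERATE"], size=len(genotypes), p=[0.4, 0.6])
    flags = rng.choice(["none", "pathogenic", "drug_response"],
                       size=len(genotypes), p=[0.85, 0.08, 0.07])
    ann = pd.DataFrame({
        "variant_id": genotypes.index,
        "gene": genes,
        "chrom": [f"chr{(i % 22) + 1}" for i in range(len(genotypes))],
        "pos": 500_000 + 10_000 * np.arange(len(genotypes)),
        "impact": impacts,
        "clinvar_flag": flags,
        "allele_freq_cohort": (genotypes.sum(axis=1) / (2 * max(config.n_patients, 1))).to_numpy(),
    }).set_index("variant_id")
    return genotypes, ann


def generate_drug_screen_db(
    n_cell_lines: int = 60,
    n_genes: int = 50,
    planted_resistance_genes: dict | None = None,
    seed: int = 0,
    drugs: tuple[str, ...] = ("5FU", "oxaliplatin"),
    k: int = 20,
    crc_quota: int = 10,
) -> dict:
    """Cell-line mutation + sensitivity tables and a tumor catalog.

    ``planted_resistance_genes`` maps gene → ``{"catalog_freq": float,
    "not_mutated": bool}``. Planted genes are mutated at >5 % of the total
    per line in every line of the first drug's resistant tail (so they
    survive phase 1 by construction); the catalog entry then decides their
    phase-3 fate, recorded in the returned truth.
    """
    if n_cell_lines < 2 * k:
        raise ValueError(f"n_cell_lines must be at least {2 * k}")
    planted_resistance_genes = planted_resistance_genes or {}
    rng = np.random.default_rng((seed, _SEED_SCREEN))
    lines = [f"CL{i + 1:04d}" for i in range(n_cell_lines)]
    tissue = np.where(np.arange(n_cell_lines) % 2 == 0, "CRC", "other")

    sens_rows = []
    for drug in drugs:
        ic50 = rng.lognormal(mean=0.0, sigma=1.0, size=n_cell_lines)
        auc = np.clip(0.3 + 0.2 * np.log(ic50) / 3 + rng.normal(0, 0.05, n_cell_lines), 0, 1)
        for cl, t, i, a in zip(lines, tissue, ic50, auc):
            sens_rows.append({"cell_line_id": cl, "drug": drug, "ic50": float(i),
                              "auc": float(a), "tissue": t})
    sensitivity = pd.DataFrame(sens_rows)
    if int((tissue == "CRC").sum()) < 2 * crc_quota:
        raise ValueError("fewer CRC lines than the per-category quota requires")

    background = [f"BG{i + 1:03d}" for i in range(n_genes)]
    mut_rows = []
    totals = {}
    for cl in lines:
        total = max(int(rng.poisson(60)), 20)
        totals[cl] = total
        weights = rng.dirichlet(np.ones(n_genes) * 0.5)
        counts = rng.multinomial(total, weights)
        for g, c in zip(background, counts):
            if c > 0:
                mut_rows.append({"cell_line_id": cl, "gene": g, "n_mutations": int(c)})
    mutations = pd.DataFrame(mut_rows)

    from .panel import rank_cell_lines

    _, resistant_tail = rank_cell_lines(sensitivity, drugs[0], k, crc_quota)
    extra = []
    for g in sorted(planted_resistance_genes):
        for cl in resistant_tail:
            extra.append({"cell_line_id": cl, "gene": g,
                          "n_mutations": max(int(round(0.10 * totals[cl])), 1)})
    if extra:
        mutations = pd.concat([mutations, pd.DataFrame(extra)], ignore_index=True)

    mutated_freq = {}
    not_mutated = set()
    truth = {}
    for g, spec in planted_resistance_genes.items():
        freq = float(spec.get("catalog_freq", 0.2))
        if spec.get("not_mutated", False):
            not_mutated.add(g)
            truth[g] = "excluded_not_mutated_list"
        else:
            mutated_freq[g] = freq
            truth[g] = "qualifies" if freq > 0.05 else "excluded_low_frequency"
    for g in background:
        f = float(rng.uniform(0.0, 0.04))
        mutated_freq[g] = f
    from .panel import TumorCatalog

    catalog = TumorCatalog(mutated_freq=mutated_freq, not_mutated=frozenset(not_mutated))
    return {
        "mutations": mutations,
        "sensitivity": sensitivity,
        "catalog": catalog,
        "resistant_tail": resistant_tail,
        "truth": truth,
    }
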