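"""Somatic variant filtering, impact classing and cohort mutation summaries.

Somatic calls enter as a MAF-like table (one row per variant per sample)
and are filtered on caller status and evidence: only ``PASS`` calls with
variant allele frequency >= 5 % supported by >= 3 alternate reads are
retained (both bounds inclusive). Functional impact follows the standard
consequence classing: nonsense, frameshift, splice-site and
transcription-start-site variants are HIGH; missense and in-frame
insertions/deletions MODERATE; synonymous LOW; everything else MODIFIER.
Association analyses count a patient as a carrier of a gene when they have
at least one HIGH or MODERATE variant in it.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IMPACT_BY_CLASS",
    "VAF_MIN",
    "ALT_READS_MIN",
    "filter_somatic",
    "classify_impact",
    "carrier_matrix",
    "gene_frequency",
    "sample_variant_counts",
    "compute_tmb",
    "kras_allele_annotate",
    "comutation_flags",
    "oncoplot_summary",
]

VAF_MIN = 0.05
ALT_READS_MIN = 3

#: variant-class -> predicted functional impact
IMPACT_BY_CLASS = {
    "nonsense": "HIGH",
    "frameshift_insertion": "HIGH",
    "frameshift_deletion": "HIGH",
    "splice_site": "HIGH",
    "tss": "HIGH",
    "missense": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "synonymous": "LOW",
    "other": "MODIFIER",
}

#: impacts that make a patient a carrier for association analyses
QUALIFYING_IMPACTS = ("HIGH", "MODERATE")

REQUIRED_COLUMNS = (
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "variant_class", "vaf", "alt_reads", "filter_status",
)


def classify_impact(variant_class: str) -> str:
    """Deterministic variant-class -> impact mapping."""
    try:
        return IMPACT_BY_CLASS[variant_class]
    except KeyError:
        raise ValueError(f"unknown variant class: {variant_class!r}") from None


def filter_somatic(
    variants: pd.DataFrame,
    vaf_min: float = VAF_MIN,
    alt_reads_min: int = ALT_READS_MIN,
    return_rejections: bool = False,
):
    """Keep PASS calls with vaf >= vaf_min and alt_reads >= alt_reads_min.

    Records missing ``vaf`` or ``alt_reads`` are rejected with reason
    ``missing_field``. With ``return_rejections`` the per-reason rejection
    counts are returned as a second value; kept + rejected always equals
    the input row count. The operation is idempotent.
    """
    missing_cols = [c for c in ("vaf", "alt_reads", "filter_status") if c not in variants.columns]
    if missing_cols:
        raise ValueError(f"variants table lacks columns: {missing_cols}")
    vaf = pd.to_numeric(variants["vaf"], errors="coerce")
    reads = pd.to_numeric(variants["alt_reads"], errors="coerce")
    missing = vaf.isna() | reads.isna()
    non_pass = ~missing & (variants["filter_status"] != "PASS")
    low_vaf = ~missing & ~non_pass & (vaf < vaf_min)
    low_reads = ~missing & ~non_pass & ~low_vaf & (reads < alt_reads_min)
    keep = ~(missing | non_pass | low_vaf | low_reads)
    kept = variants.loc[keep].copy()
    if return_rejections:
        reasons = {
            "missing_field": int(missing.sum()),
            "non_pass": int(non_pass.sum()),
            "low_vaf": int(low_vaf.sum()),
            "low_alt_reads": int(low_reads.sum()),
        }
        return kept, reasons
    return kept


def _ensure_impact(variants: pd.DataFrame) -> pd.Series:
    if "impact" in variants.columns and variants["impact"].notna().all():
        return variants["impact"]
    return variants["variant_class"].map(classify_impact)


def carrier_matrix(
    variants: pd.DataFrame,
    patients,
    impacts: tuple[str, ...] = QUALIFYING_IMPACTS,
) -> pd.DataFrame:
    """Patients × genes count matrix of qualifying variants.

    ``patients`` fixes the row index (zero-variant patients included).
    A patient carries a gene when the count is > 0. Output is invariant to
    input row order: rows and columns are sorted.
    """
    patients = list(patients)
    if variants.empty:
        return pd.DataFrame(0, index=sorted(patients), columns=[], dtype=np.int64)
    v = variants.copy()
    v["impact"] = _ensure_impact(v)
    v = v[v["impact"].isin(impacts)]
    counts = v.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
    counts = counts.reindex(index=sorted(patients), fill_value=0)
    counts = counts[sorted(counts.columns)]
    return counts.astype(np.int64)


def gene_frequency(carrier: pd.DataFrame) -> pd.DataFrame:
    """Per-gene carrier counts and fraction of mutated patients."""
    if carrier.shape[0] == 0:
        raise ValueError("empty cohort")
    carriers = (carrier > 0).sum(axis=0)
    out = pd.DataFrame({
        "carriers": carriers.astype(int),
        "n_patients": carrier.shape[0],
    })
    out["frequency"] = out["carriers"] / out["n_patients"]
    # frequency descending, ties by gene symbol for stable output
    return out.sort_index().sort_values("frequency", ascending=False, kind="stable")


def sample_variant_counts(variants: pd.DataFrame, patients=None) -> dict:
    """Per-sample variant totals with HIGH/MODERATE splits and cohort medians.

    Patients without any variant are included with count 0 when
    ``patients`` is given. Medians are the usual mid-point of the two
    central order statistics for even cohort sizes.
    """
    v = variants.copy()
    if not v.empty:
        v["impact"] = _ensure_impact(v)
    idx = sorted(patients) if patients is not None else sorted(v["sample_id"].unique())
    total = v.groupby("sample_id").size().reindex(idx, fill_value=0)
    high = v[v.get("impact", pd.Series(dtype=object)) == "HIGH"].groupby("sample_id").size().reindex(idx, fill_value=0) if not v.empty else pd.Series(0, index=idx)
    mod = v[v.get("impact", pd.Series(dtype=object)) == "MODERATE"].groupby("sample_id").size().reindex(idx, fill_value=0) if not v.empty else pd.Series(0, index=idx)
    table = pd.DataFrame({"total": total, "high": high, "moderate": mod})
    return {
        "per_sample": table,
        "median_total": float(np.median(table["total"])) if len(table) else float("nan"),
        "range_total": (int(table["total"].min()), int(table["total"].max())) if len(table) else (0, 0),
        "median_high": float(np.median(table["high"])) if len(table) else float("nan"),
        "median_moderate": float(np.median(table["moderate"])) if len(table) else float("nan"),
    }


def compute_tmb(variants: pd.DataFrame, panel_size_mb: float, patients=None) -> pd.Series:
    """Per-sample tumor mutational burden: filtered variants / Mb of target."""
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be positive")
    if len(variants) == 0:
        idx = sorted(patients) if patients is not None else []
        return pd.Series(0.0, index=idx)
    idx = sorted(patients) if patients is not None else sorted(variants["sample_id"].unique())
    counts = variants.groupby("sample_id").size().reindex(idx, fill_value=0)
    return counts / panel_size_mb


_HGVS_SUB = re.compile(r"^p\.(?:\()?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})(?:\))?$")

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}


def _parse_hgvs_sub(p: str):
    """(ref_aa, residue, alt_aa) in one-letter code, or None if not a substitution."""
    if not isinstance(p, str):
        return None
    m = _HGVS_SUB.match(p.strip())
    if not m:
        return None
    ref, pos, alt = m.groups()
    ref1 = _AA3TO1.get(ref.capitalize(), ref.upper() if len(ref) == 1 else None)
    alt1 = _AA3TO1.get(alt.capitalize(), alt.upper() if len(alt) == 1 else None)
    if ref1 is None or alt1 is None:
        return None
    return ref1, int(pos), alt1


def kras_allele_annotate(variants: pd.DataFrame, patients=None) -> pd.DataFrame:
    """Per-patient KRAS allele flags: any variant, codon 12/13, G12D.

    ``KRAS_12D`` is a substitution to aspartate at residue 12 (``p.G12D``
    or ``p.Gly12Asp``); ``KRAS_codon12_13`` any substitution at residues
    12 or 13. Unparseable protein changes on KRAS records leave the
    codon flags false but still set ``KRAS_any``.
    """
    idx = sorted(patients) if patients is not None else sorted(variants["sample_id"].unique())
    flags = pd.DataFrame(False, index=idx, columns=["KRAS_any", "KRAS_codon12_13", "KRAS_12D"])
    kras = variants[variants["gene"] == "KRAS"]
    for _, row in kras.iterrows():
        s = row["sample_id"]
        if s not in flags.index:
            continue
        flags.loc[s, "KRAS_any"] = True
        parsed = _parse_hgvs_sub(row.get("protein_change"))
        if parsed is None:
            continue
        _, residue, alt = parsed
        if residue in (12, 13):
            flags.loc[s, "KRAS_codon12_13"] = True
            if residue == 12 and alt == "D":
                flags.loc[s, "KRAS_12D"] = True
    return flags


def comutation_flags(
    carrier: pd.DataFrame,
    kras_flags: pd.DataFrame,
    apc_truncating: pd.Series,
) -> pd.DataFrame:
    """Oncodriver co-mutation indicators per patient.

    ``apc_truncating`` marks patients with an APC frameshift or nonsense
    variant. Emits KRAS(codon 12/13)+TP53, KRAS-12D+TP53 and the
    APC(truncating)+KRAS+TP53 triple.
    """
    idx = carrier.index
    tp53 = carrier["TP53"] > 0 if "TP53" in carrier.columns else pd.Series(False, index=idx)
    kras_any = kras_flags["KRAS_any"].reindex(idx, fill_value=False)
    k1213 = kras_flags["KRAS_codon12_13"].reindex(idx, fill_value=False)
    k12d = kras_flags["KRAS_12D"].reindex(idx, fill_value=False)
    apc_t = apc_truncating.reindex(idx, fill_value=False).astype(bool)
    return pd.DataFrame({
        "KRAS1213_TP53": k1213 & tp53,
        "KRAS12D_TP53": k12d & tp53,
        "APCtrunc_KRAS_TP53": apc_t & kras_any & tp53,
    })


def apc_truncating_flags(variants: pd.DataFrame, patients=None) -> pd.Series:
    """Patients with an APC frameshift or nonsense variant."""
    idx = sorted(patients) if patients is not None else sorted(variants["sample_id"].unique())
    apc = variants[
        (variants["gene"] == "APC")
        & variants["variant_class"].isin(
            ["frameshift_insertion", "frameshift_deletion", "nonsense"]
        )
    ]
    flag = pd.Series(False, index=idx)
    hits = [s for s in apc["sample_id"].unique() if s in flag.index]
    flag.loc[hits] = True
    return flag


def oncoplot_summary(variants: pd.DataFrame, top_n: int = 20, patients=None) -> pd.DataFrame:
    """Top-N genes by carrier frequency × variant-class counts.

    Genes are ordered by carrier frequency descending with ties broken by
    symbol, so output is stable across runs and input orderings.
    """
    v = variants.copy()
    v["impact"] = _ensure_impact(v)
    qual = v[v["impact"].isin(QUALIFYING_IMPACTS)]
    cm = carrier_matrix(v, patients if patients is not None else v["sample_id"].unique())
    freq = (cm > 0).sum(axis=0)
    order = sorted(freq.index, key=lambda g: (-freq[g], g))[:top_n]
    classes = sorted(IMPACT_BY_CLASS)
    rows = []
    for g in order:
        cts = Counter(qual.loc[qual["gene"] == g, "variant_class"])
        rows.append({"gene": g, "carriers": int(freq[g]), **{c: cts.get(c, 0) for c in classes}})
    return pd.DataFrame(rows)
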