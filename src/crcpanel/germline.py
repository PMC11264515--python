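"""Germline variant prioritization and permutation-based survival association.

Germline variants annotated with predicted functional impact and
ClinVar-style flags are prioritized by the cohort-level carrier frequency
of HIGH-impact variants per gene (5 % floor). Association with outcome
uses a binary phenotype from recurrence-free survival dichotomized at
3 years — an accepted endpoint for adjuvant 5-FU-based regimens — tested
per variant with the allelic chi-square (2×2 table of allele counts,
Pearson, 1 df, no continuity correction, the PLINK ``--assoc`` allelic
test), and corrected family-wise with the Monte-Carlo max(T) permutation
procedure: phenotype labels are permuted, the maximum chi-square across
variants recorded per permutation, and each variant's adjusted p is the
add-one empirical tail probability of that maximum distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survival import breslow_test, km_estimate

__all__ = [
    "prioritize_germline",
    "rfs_dichotomize",
    "allelic_chisq",
    "maxt_permutation",
    "manhattan_table",
    "genotype_km",
]

MISSING = -1  # missing genotype code in integer matrices


def _as_matrix(genotypes: pd.DataFrame) -> np.ndarray:
    g = genotypes.to_numpy(dtype=float)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int64)
    bad = ~np.isin(g, [MISSING, 0, 1, 2])
    if bad.any():
        raise ValueError("genotype codes must be 0/1/2 or missing")
    return g


def prioritize_germline(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    min_gene_freq: float = 0.05,
) -> dict:
    """Shortlist genes by HIGH-impact carrier frequency; flag ClinVar variants.

    ``variants`` indexes the rows of ``genotypes`` (variants × patients)
    and carries ``gene``, ``impact`` and ``clinvar_flag`` columns. A
    patient carries a gene when any HIGH variant of that gene has genotype
    >= 1. Genes at frequency >= ``min_gene_freq`` are shortlisted and
    their ClinVar/InterVar-flagged variants enumerated. Per-sample total
    variant counts are reported as a summary.
    """
    if not variants.index.equals(genotypes.index):
        variants = variants.loc[genotypes.index]
    g = _as_matrix(genotypes)
    carrier_any = g >= 1  # missing (-1) is False
    n_pat = genotypes.shape[1]

    high = variants["impact"] == "HIGH"
    gene_freq = {}
    for gene, rows in variants.groupby("gene").groups.items():
        sel = variants.index.isin(rows) & high.to_numpy()
        if not sel.any():
            continue
        carriers = carrier_any[sel].any(axis=0).sum()
        gene_freq[gene] = carriers / n_pat
    freq = pd.Series(gene_freq, dtype=float).sort_values(ascending=False)
    shortlist = freq[freq >= min_gene_freq]

    flagged = variants[
        variants["gene"].isin(shortlist.index)
        & (variants["clinvar_flag"].isin(["pathogenic", "drug_response"]))
    ]
    per_sample = pd.Series((g >= 1).sum(axis=0), index=genotypes.columns)
    return {
        "gene_high_freq": freq,
        "shortlisted_genes": shortlist,
        "flagged_variants": flagged,
        "per_sample_counts": per_sample,
        "median_per_sample": float(np.median(per_sample)) if n_pat else float("nan"),
    }


def rfs_dichotomize(endpoints: pd.DataFrame, cut_years: float = 3.0) -> pd.Series:
    """Binary RFS phenotype: recurrence within ``cut_years`` vs beyond.

    Cases (1) recur at or before the cut; controls (0) are followed beyond
    the cut (with or without a later event); patients censored before the
    cut without recurrence are indeterminate and coded missing (NaN).
    """
    cut = cut_years * 12.0
    t = endpoints["rfs_months"].astype(float)
    e = endpoints["rfs_event"].astype(bool)
    pheno = pd.Series(np.nan, index=endpoints.index, name="rfs_le_cut")
    pheno[e & (t <= cut)] = 1.0
    pheno[t > cut] = 0.0
    return pheno


def allelic_chisq(genotypes_for_variant, phenotype) -> tuple[float, float, np.ndarray]:
    """Allelic chi-square for one variant against a binary phenotype.

    Builds the 2×2 allele-count table (rows cases/controls, columns
    alt/ref over 2n alleles) after pairwise-dropping missing genotypes or
    phenotypes, and returns the Pearson chi-square (1 df, no continuity
    correction), its p, and the table. Monomorphic variants give p = 1.
    """
    g = np.asarray(genotypes_for_variant, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = (g != MISSING) & ~np.isnan(g) & ~np.isnan(y)
    g, y = g[ok], y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must have two classes after missing removal")
    table = np.zeros((2, 2))
    for row, cls in ((0, 1.0), (1, 0.0)):  # row 0 cases, row 1 controls
        sel = y == cls
        alt = g[sel].sum()
        table[row] = [alt, 2 * sel.sum() - alt]
    stat = _pearson_chi2_2x2(table)
    if stat == 0.0 and (table[:, 0].sum() == 0 or table[:, 1].sum() == 0):
        return 0.0, 1.0, table  # monomorphic
    from scipy.stats import chi2

    return float(stat), float(chi2.sf(stat, 1)), table


def _pearson_chi2_2x2(t: np.ndarray) -> float:
    a, b = t[0]
    c, d = t[1]
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    return float(n * (a * d - b * c) ** 2 / denom)


def maxt_permutation(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Family-wise empirical p per variant via max(T) phenotype permutation.

    Missing phenotypes are dropped; missing genotypes are excluded
    per-variant (pairwise). For each permutation the maximum allelic
    chi-square across variants is recorded; the adjusted p for variant i is
    ``(1 + #{perm max >= observed_i}) / (n_perm + 1)``. Per-variant plain
    permutation p values are returned alongside. Fully vectorized; a fixed
    seed gives identical output regardless of variant row order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    y_full = np.asarray(phenotype.reindex(genotypes.columns), dtype=float)
    keep = ~np.isnan(y_full)
    y = y_full[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must have two classes")
    g = _as_matrix(genotypes.loc[:, genotypes.columns[keep]])
    m, n = g.shape
    present = (g != MISSING).astype(np.float64)
    galt = np.where(g == MISSING, 0, g).astype(np.float64)

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm + 1))
    perms[:, 0] = y  # observed labels first
    for b in range(1, n_perm + 1):
        perms[:, b] = rng.permutation(y)

    # per-variant, per-permutation allele tables via matrix products
    alt_cases = galt @ perms                     # m × (B+1)
    n_cases = 2.0 * (present @ perms)            # alleles among cases
    alt_total = galt.sum(axis=1, keepdims=True)  # m × 1
    n_total = 2.0 * present.sum(axis=1, keepdims=True)

    a = alt_cases
    b_ = n_cases - alt_cases
    c = alt_total - alt_cases
    d = (n_total - n_cases) - c
    r1, r2 = a + b_, c + d
    c1, c2 = a + c, b_ + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_all = np.where(denom > 0, n_total * (a * d - b_ * c) ** 2 / denom, 0.0)

    obs = chi2_all[:, 0]
    null = chi2_all[:, 1:]
    max_null = null.max(axis=0)
    p_maxt = (1 + (max_null[None, :] >= obs[:, None]).sum(axis=1)) / (n_perm + 1)
    p_point = (1 + (null >= obs[:, None]).sum(axis=1)) / (n_perm + 1)

    from scipy.stats import chi2 as chi2_dist

    return pd.DataFrame({
        "chi2": obs,
        "p_asymptotic": chi2_dist.sf(obs, 1),
        "p_perm": p_point,
        "p_maxt": p_maxt,
    }, index=genotypes.index)


def manhattan_table(variants: pd.DataFrame, results: pd.DataFrame, p_col: str = "p_maxt") -> pd.DataFrame:
    """Tidy per-variant (chrom, pos, p, −log10 p) table sorted by position."""
    out = variants[["chrom", "pos"]].join(results[[p_col]])
    out["neg_log10_p"] = -np.log10(out[p_col].clip(lower=np.finfo(float).tiny))
    out.loc[out[p_col] >= 1.0, "neg_log10_p"] = 0.0
    return out.sort_values(["chrom", "pos"]).reset_index(names="variant_id")


def genotype_km(
    genotypes_for_variant: pd.Series,
    endpoints: pd.DataFrame,
    endpoint: str = "os",
    model: str = "wt vs het vs hom",
) -> dict:
    """Kaplan–Meier comparison across genotype groups with the Breslow test.

    ``model`` is ``"wt vs het vs hom"`` (empty classes collapse away) or
    ``"wt vs carrier"``. Returns curves, the test statistic and p, and
    group sizes. Raises when only one non-empty group remains.
    """
    g = genotypes_for_variant.reindex(endpoints.index)
    ok = g.notna() & (g != MISSING)
    idx = endpoints.index[ok & ~endpoints["exclude_survival"]]
    g = g.loc[idx].astype(int)
    if model == "wt vs carrier":
        labels = np.where(g >= 1, "carrier", "wild_type")
    elif model == "wt vs het vs hom":
        labels = np.where(g == 0, "wild_type", np.where(g == 1, "het", "hom"))
    else:
        raise ValueError(f"unknown model {model!r}")
    labels = pd.Series(labels, index=idx)
    if labels.nunique() < 2:
        raise ValueError("only one non-empty genotype group")
    t = endpoints.loc[idx, f"{endpoint}_months"].to_numpy()
    e = endpoints.loc[idx, f"{endpoint}_event"].to_numpy()
    stat, p = breslow_test(t, e, labels.to_numpy())
    curves = km_estimate(t, e, labels.to_numpy())
    return {
        "statistic": stat,
        "p": p,
        "curves": curves,
        "group_sizes": labels.value_counts().to_dict(),
    }
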