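"""Genome-instability surrogates: MSI, MMR-deficiency, CNV significance.

Three classifiers used on targeted-panel tumor data:

* microsatellite instability (MSI) from the fraction of unstable
  microsatellite sites, with the conventional 20 % cut-off;
* mismatch-repair deficiency (MMR-D) from the density of small
  insertions/deletions inside homopolymer runs of the target region
  (> 1.5 indels/Mb);
* copy-number calls from segment log2 ratios and B-allele frequencies,
  thresholded under a clonal-fraction model: with an effective aberrant
  cell fraction ``f = purity × clonality``, a mono-allelic deletion is
  expected at log2((2 − f)/2) and a single-copy gain at log2((2 + f)/2),
  so segments must exceed those bounds (and show a BAF inside a window
  around 0.5) to be called. Segments with fewer than three bins, or whose
  bin-level log2 values are not significantly different from reference
  (copy-neutral) bins by Student's t-test, are excluded.

Coordinates are 0-based half-open internally; VCF positions (1-based)
are converted on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "HomopolymerRegion",
    "PurityThresholds",
    "find_homopolymers",
    "homopolymer_indel_density",
    "classify_mmrd",
    "classify_msi",
    "derive_cnv_thresholds",
    "filter_cnv_segments",
    "summarize_cnv",
]

#: minimum run length counting as a homopolymer ("more than four repeat bases")
MIN_RUN = 5
#: MMR-D cut-off, indels in homopolymer regions per Mb (strict >)
MMRD_DENSITY_THRESHOLD = 1.5
#: MSI-high cut-off on the unstable-site fraction (strict >)
MSI_FRACTION_THRESHOLD = 0.20


@dataclass(frozen=True)
class HomopolymerRegion:
    """A maximal run of a single base, 0-based half-open."""

    chrom: str
    start: int
    end: int
    base: str

    @property
    def run_length(self) -> int:
        return self.end - self.start


def find_homopolymers(sequence: str, chrom: str = "chr1", min_run: int = MIN_RUN) -> list[HomopolymerRegion]:
    """All maximal single-base runs of length >= ``min_run``, sorted by start.

    ``N`` (or any non-ACGT character) never extends a run.
    """
    seq = sequence.upper()
    out: list[HomopolymerRegion] = []
    n = len(seq)
    i = 0
    while i < n:
        b = seq[i]
        j = i + 1
        while j < n and seq[j] == b:
            j += 1
        if b in "ACGT" and j - i >= min_run:
            out.append(HomopolymerRegion(chrom, i, j, b))
        i = j
    return out


def homopolymer_indel_density(
    indel_positions,
    regions: list[HomopolymerRegion],
    target_mb: float,
    chrom: str | None = None,
) -> float:
    """Indels per Mb whose anchored base falls inside a homopolymer region.

    ``indel_positions`` are 1-based VCF POS values (position of the anchored
    base). Each indel counts at most once even if regions were to overlap.
    """
    if target_mb <= 0:
        raise ValueError("target_mb must be positive")
    if not regions:
        return 0.0
    starts = np.array([r.start for r in regions])
    ends = np.array([r.end for r in regions])
    count = 0
    for pos in indel_positions:
        p0 = int(pos) - 1  # to 0-based
        if np.any((starts <= p0) & (p0 < ends)):
            count += 1
    return count / float(target_mb)


def classify_mmrd(density: float, threshold: float = MMRD_DENSITY_THRESHOLD) -> bool:
    """MMR-deficient iff the homopolymer-indel density strictly exceeds the cut-off."""
    if density < 0:
        raise ValueError("density must be non-negative")
    return density > threshold


def classify_msi(unstable_fraction: float, threshold: float = MSI_FRACTION_THRESHOLD) -> str:
    """``"MSI-high"`` iff the unstable-site fraction strictly exceeds the cut-off, else ``"MSS"``."""
    if not 0.0 <= unstable_fraction <= 1.0:
        raise ValueError("unstable_fraction must lie in [0, 1]")
    return "MSI-high" if unstable_fraction > threshold else "MSS"


@dataclass(frozen=True)
class PurityThresholds:
    """CNV calling bounds under the clonal-fraction model."""

    purity: float
    clonality: float
    log2_del: float
    log2_dup: float
    baf_del_window: tuple[float, float]
    baf_dup_window: tuple[float, float]

    @property
    def f_eff(self) -> float:
        return self.purity * self.clonality

    def rounded(self) -> dict:
        """Report-style values, rounded to 3 decimals."""
        return {
            "log2_del": round(self.log2_del, 3),
            "log2_dup": round(self.log2_dup, 3),
            "baf_del_window": tuple(round(v, 3) for v in self.baf_del_window),
            "baf_dup_window": tuple(round(v, 3) for v in self.baf_dup_window),
        }


def derive_cnv_thresholds(
    purity: float,
    clonality: float,
    *,
    del_window_div: float = 2.0,
    dup_window_div: float = 6.0,
) -> PurityThresholds:
    """Log2 and BAF calling bounds for an aberration at fraction f = purity × clonality.

    log2 bounds sit at the expected depth ratio of a mono-allelic loss,
    log2((2 − f)/2), and a single-copy gain, log2((2 + f)/2). BAF windows
    are symmetric about 0.5 with half-widths f/2 (deletions) and f/6
    (duplications); the divisors are overridable.
    """
    if not (0 < purity <= 1) or not (0 < clonality <= 1):
        raise ValueError("purity and clonality must lie in (0, 1]")
    f = purity * clonality
    return PurityThresholds(
        purity=purity,
        clonality=clonality,
        log2_del=math.log2((2 - f) / 2),
        log2_dup=math.log2((2 + f) / 2),
        baf_del_window=(0.5 - f / del_window_div, 0.5 + f / del_window_div),
        baf_dup_window=(0.5 - f / dup_window_div, 0.5 + f / dup_window_div),
    )


def filter_cnv_segments(
    segments: pd.DataFrame,
    thresholds: PurityThresholds,
    reference_log2,
    alpha: float = 0.05,
    min_bins: int = 3,
) -> pd.DataFrame:
    """Assign a call to every segment: deletion / duplication / neutral / excluded.

    ``segments`` needs columns ``sample_id, chrom, start, end, n_bins,
    bin_log2, baf`` where ``bin_log2`` holds a list/array of per-bin log2
    ratios (or a comma-separated string). A segment is ``excluded`` when it
    has fewer than ``min_bins`` bins or its bins do not differ from the
    ``reference_log2`` sample (two-sided pooled-variance Student t-test,
    p >= alpha). Otherwise it is a deletion/duplication when its mean log2
    crosses the bound and its BAF lies in the matching window, else neutral.
    """
    ref = np.asarray(reference_log2, dtype=float)
    if ref.size < 2:
        raise ValueError("reference_log2 needs at least two values")
    seg = segments.copy()
    calls: list[str] = []
    means: list[float] = []
    pvals: list[float] = []
    for _, row in seg.iterrows():
        bins = row["bin_log2"]
        if isinstance(bins, str):
            bins = [float(x) for x in bins.split(",") if x != ""]
        bins = np.asarray(bins, dtype=float)
        if bins.size == 0:
            raise ValueError("segment with empty bin_log2")
        mean = float(bins.mean())
        means.append(mean)
        if bins.size < min_bins:
            calls.append("excluded")
            pvals.append(float("nan"))
            continue
        _, p = sps.ttest_ind(bins, ref, equal_var=True)
        pvals.append(float(p))
        if p >= alpha:
            calls.append("excluded")
            continue
        baf = float(row["baf"])
        lo_d, hi_d = thresholds.baf_del_window
        lo_u, hi_u = thresholds.baf_dup_window
        if mean < thresholds.log2_del and lo_d <= baf <= hi_d:
            calls.append("deletion")
        elif mean > thresholds.log2_dup and lo_u <= baf <= hi_u:
            calls.append("duplication")
        else:
            calls.append("neutral")
    seg["mean_log2"] = means
    seg["t_p"] = pvals
    seg["call"] = calls
    return seg


def summarize_cnv(called: pd.DataFrame) -> dict:
    """Per-sample call counts and cohort size summary of non-neutral calls.

    Sizes are ``end − start`` in base pairs, reported in Mbp; medians are
    over deletion/duplication calls only.
    """
    out: dict = {"per_sample": {}, "n_deletion": 0, "n_duplication": 0,
                 "n_neutral": 0, "n_excluded": 0, "median_size_mbp": None}
    if called.empty:
        return out
    sizes = []
    for sample, grp in called.groupby("sample_id"):
        cts = grp["call"].value_counts().to_dict()
        out["per_sample"][sample] = {
            k: int(cts.get(k, 0)) for k in ("deletion", "duplication", "neutral", "excluded")
        }
    for k in ("deletion", "duplication", "neutral", "excluded"):
        out[f"n_{k}"] = int((called["call"] == k).sum())
    aberrant = called[called["call"].isin(["deletion", "duplication"])]
    if not aberrant.empty:
        sizes = (aberrant["end"] - aberrant["start"]) / 1e6
        out["median_size_mbp"] = float(np.median(sizes))
    return out
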