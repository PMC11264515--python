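"""Survival endpoints, Kaplan–Meier curves, the Gehan–Breslow test and the
gene-set prognostic screen.

Endpoints follow the usual surgical-cohort definitions: overall survival
(OS) runs from resection of the primary tumor to death from any cause;
recurrence-free survival (RFS) from resection to recurrence, with deaths
in remission and last controls in remission censored. Metastatic
(stage IV) patients are excluded from survival analyses.

Curves are compared with the Gehan–Breslow generalized Wilcoxon test — a
weighted log-rank statistic whose weight at each event time is the total
number at risk, the meaning of "Breslow test" in SPSS. The k-group version
uses a chi-square reference with k − 1 degrees of freedom.

The prognostic screen mirrors a two-stage design: stage 1 tests every gene
mutated in at least 10 % of the cohort (carrier vs non-carrier) within
each treatment stratum; stage 2 groups the genes with crude p < 0.05 into
a set per stratum, classifies patients by how many set genes are mutated
(0 / 1 / >1) and tests the set in every stratum, applying
Benjamini–Hochberg adjustment over the full family of tests the screen
executed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "SurvivalEndpoint",
    "KMCurve",
    "build_endpoints",
    "km_estimate",
    "breslow_test",
    "logrank_test",
    "median_split",
    "geneset_groups",
    "prognostic_screen",
]


@dataclass(frozen=True)
class SurvivalEndpoint:
    patient_id: str
    time: float
    event: bool
    endpoint_name: str  # "RFS" or "OS"


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray
    median: float | None
    median_ci: tuple[float, float] | None
    n: int
    n_events: int


def build_endpoints(clinical: pd.DataFrame) -> pd.DataFrame:
    """RFS/OS endpoint table from a clinical table with precomputed times.

    Expects columns ``patient_id, stage, rfs_months, rfs_event, os_months,
    os_event``. Adds ``exclude_survival`` for stage IV patients. Raises on
    negative or missing times.
    """
    req = ["patient_id", "stage", "rfs_months", "rfs_event", "os_months", "os_event"]
    missing = [c for c in req if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns: {missing}")
    out = clinical[req].copy()
    for col in ("rfs_months", "os_months"):
        t = pd.to_numeric(out[col], errors="coerce")
        if t.isna().any() or (t < 0).any():
            raise ValueError(f"negative or missing {col}")
        out[col] = t
    out["rfs_event"] = out["rfs_event"].astype(bool)
    out["os_event"] = out["os_event"].astype(bool)
    out["exclude_survival"] = out["stage"].astype(str) == "IV"
    return out.set_index("patient_id")


def km_estimate(times, events, groups) -> dict[str, KMCurve]:
    """Kaplan–Meier curve per group (ties decrement simultaneously)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        m = groups == g
        if m.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        tab = kmf.event_table
        med = kmf.median_survival_time_
        try:
            from lifelines.utils import median_survival_times

            ci = median_survival_times(kmf.confidence_interval_)
            lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
            median_ci = None if np.isinf(lo) and np.isinf(hi) else (lo, hi)
        except Exception:  # pragma: no cover - CI is informational
            median_ci = None
        curves[str(g)] = KMCurve(
            group=str(g),
            times=tab.index.to_numpy(dtype=float),
            at_risk=tab["at_risk"].to_numpy(dtype=float),
            survival=kmf.survival_function_["KM_estimate"].to_numpy(),
            median=None if np.isinf(med) else float(med),
            median_ci=median_ci,
            n=int(m.sum()),
            n_events=int(events[m].sum()),
        )
    return curves


def _weighted_logrank(times, events, groups, weight: str) -> tuple[float, float, int]:
    """k-group weighted log-rank chi-square.

    ``weight``: "breslow" uses the number at risk at each event time
    (Gehan–Breslow generalized Wilcoxon); "logrank" uses unit weights.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist(), key=str)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    if events.sum() == 0:
        return 0.0, 1.0, k
    gidx = np.array([labels.index(g) for g in groups])
    event_times = np.unique(times[events])
    U = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        if n_j <= 1:
            continue
        d_j = int((events & (times == t)).sum())
        if d_j == 0:
            continue
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_ij = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        w = float(n_j) if weight == "breslow" else 1.0
        exp = d_j * n_ij / n_j
        U += w * (d_ij - exp)
        # multivariate hypergeometric covariance of d_ij
        frac = n_ij / n_j
        hyper = d_j * (n_j - d_j) / max(n_j - 1, 1)
        cov = hyper * (np.diag(frac) - np.outer(frac, frac))
        V += (w ** 2) * cov
    # drop one group: U sums to zero, V is singular
    U_r = U[:-1]
    V_r = V[:-1, :-1]
    try:
        stat = float(U_r @ np.linalg.solve(V_r, U_r))
    except np.linalg.LinAlgError:
        stat = float(U_r @ np.linalg.pinv(V_r) @ U_r)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, k - 1))
    return stat, p, k


def breslow_test(times, events, groups) -> tuple[float, float]:
    """Gehan–Breslow generalized Wilcoxon test (at-risk-count weights)."""
    stat, p, _ = _weighted_logrank(times, events, groups, "breslow")
    return stat, p


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Standard (unit-weight) log-rank test."""
    stat, p, _ = _weighted_logrank(times, events, groups, "logrank")
    return stat, p


def median_split(values) -> np.ndarray:
    """Binary grouping at the median; ties go to the lower group.

    Returns a boolean array, True for values strictly above the median.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    med = float(np.median(v))
    high = v > med
    if high.all() or (~high).all():
        raise ValueError("degenerate median split: all values identical")
    return high


def geneset_groups(carrier: pd.DataFrame, gene_set) -> pd.Series:
    """Per-patient carriage category over a gene set: "0", "1" or ">1".

    Counts set genes with at least one qualifying variant. Unknown gene
    symbols raise.
    """
    genes = list(gene_set)
    unknown = [g for g in genes if g not in carrier.columns]
    if unknown:
        raise ValueError(f"genes absent from carrier matrix: {unknown}")
    n_mut = (carrier[genes] > 0).sum(axis=1)
    return pd.Series(
        np.where(n_mut == 0, "0", np.where(n_mut == 1, "1", ">1")),
        index=carrier.index,
        name="geneset_group",
    )


def _stratum_mask(endpoints: pd.DataFrame, clinical: pd.DataFrame, stratum: str) -> pd.Series:
    base = ~endpoints["exclude_survival"]
    if stratum == "all":
        return base
    treated = clinical.set_index("patient_id")["regimen"].reindex(endpoints.index) != "none"
    if stratum == "treated":
        return base & treated
    if stratum == "untreated":
        return base & ~treated
    raise ValueError(f"unknown stratum {stratum!r}")


def prognostic_screen(
    carrier: pd.DataFrame,
    endpoints: pd.DataFrame,
    clinical: pd.DataFrame,
    min_gene_freq: float = 0.10,
    alpha: float = 0.05,
    strata: tuple[str, ...] = ("all", "untreated", "treated"),
    endpoint: str = "os",
    test: str = "breslow",
    union_sets: bool = False,
) -> dict:
    """Two-stage gene-set prognostic screen.

    Stage 1: per-gene Gehan–Breslow tests (carrier vs non-carrier) within
    each stratum, restricted to genes mutated in >= ``min_gene_freq`` of
    the cohort. Stage 2: per stratum, genes with crude p < ``alpha`` form
    a set; each set is categorized by 0/1/>1 mutated genes and tested in
    every stratum. With ``union_sets`` a single cross-stratum union set is
    screened instead. B-H adjustment runs over the full family of stage-1
    and stage-2 tests.

    Returns ``{"single_gene": DataFrame, "gene_sets": DataFrame,
    "sets": {stratum: [genes]}, "family_size": int}``.
    """
    test_fn = breslow_test if test == "breslow" else logrank_test
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    freq = (carrier > 0).mean(axis=0)
    tested_genes = [g for g in carrier.columns if freq[g] >= min_gene_freq]

    single_rows = []
    for stratum in strata:
        mask = _stratum_mask(endpoints, clinical, stratum)
        idx = endpoints.index[mask]
        if len(idx) < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 patients")
        t = endpoints.loc[idx, tcol].to_numpy()
        e = endpoints.loc[idx, ecol].to_numpy()
        for g in tested_genes:
            grp = (carrier.loc[idx, g] > 0).to_numpy()
            if grp.all() or not grp.any():
                continue
            stat, p = test_fn(t, e, np.where(grp, "carrier", "wild_type"))
            single_rows.append({
                "gene": g, "stratum": stratum, "n": len(idx),
                "n_carriers": int(grp.sum()), "statistic": stat, "p_crude": p,
            })
    single = pd.DataFrame(single_rows)

    sets: dict[str, list[str]] = {}
    for stratum in strata:
        sub = single[(single["stratum"] == stratum) & (single["p_crude"] < alpha)]
        sets[stratum] = sorted(sub["gene"].tolist())
    if union_sets:
        union = sorted(set(g for gl in sets.values() for g in gl))
        sets = {s: union for s in strata}

    set_rows = []
    for origin, genes in sets.items():
        if not genes:
            continue
        cats = geneset_groups(carrier, genes)
        for stratum in strata:
            mask = _stratum_mask(endpoints, clinical, stratum)
            idx = endpoints.index[mask]
            grp = cats.loc[idx]
            if grp.nunique() < 2:
                continue
            stat, p = test_fn(
                endpoints.loc[idx, tcol].to_numpy(),
                endpoints.loc[idx, ecol].to_numpy(),
                grp.to_numpy(),
            )
            sizes = grp.value_counts().to_dict()
            set_rows.append({
                "set_origin": origin, "genes": ",".join(genes), "stratum": stratum,
                "n": len(idx), "n0": int(sizes.get("0", 0)), "n1": int(sizes.get("1", 0)),
                "n_multi": int(sizes.get(">1", 0)), "statistic": stat, "p_crude": p,
            })
    gene_sets = pd.DataFrame(set_rows)

    family = len(single) + len(gene_sets)
    if family:
        all_p = np.concatenate([
            single["p_crude"].to_numpy() if len(single) else np.empty(0),
            gene_sets["p_crude"].to_numpy() if len(gene_sets) else np.empty(0),
        ])
        adj = bh_adjust(all_p)
        if len(single):
            single = single.assign(p_adj=adj[: len(single)])
        if len(gene_sets):
            gene_sets = gene_sets.assign(p_adj=adj[len(single):])
    return {"single_gene": single, "gene_sets": gene_sets, "sets": sets, "family_size": family}
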