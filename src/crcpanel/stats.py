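"""Exact and rank-based association statistics with FDR adjustment.

Carrier-status vs clinical-covariate associations in the cohort analyses
use Fisher's exact test (2×2 and its Freeman–Halton r×c generalization),
the Kruskal–Wallis test for continuous variables across groups, Spearman's
rho for correlations, and Benjamini–Hochberg step-up adjustment across an
explicitly declared test family.

Two-sided Fisher p-values follow the probability-mass convention used by
mainstream statistical software: the p-value is the total probability of
all margin-consistent tables whose hypergeometric (multivariate
hypergeometric for r×c) probability does not exceed that of the observed
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "TestResult",
    "build_contingency",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "kruskal_wallis",
    "spearman_rho",
    "bh_adjust",
]

# Relative slack when comparing table probabilities, guarding against
# floating-point noise in "probability <= observed probability".
_REL_EPS = 1e-7


@dataclass
class ContingencyTable:
    """An r×c count table with row/column labels."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match counts shape")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class TestResult:
    """One association test: statistic, crude and adjusted p, sample size."""

    test_name: str
    grouping: str
    statistic: float
    p_crude: float
    n: int
    p_adj: float | None = None
    family_size: int | None = None
    extra: dict = field(default_factory=dict)


def build_contingency(
    clinical: pd.DataFrame,
    carrier: pd.Series,
    row_var: str,
    collapse_map: dict[str, str | None],
    carrier_labels: tuple[str, str] = ("wild_type", "mutant"),
) -> ContingencyTable:
    """Cross-tabulate a collapsed clinical variable against carrier status.

    ``collapse_map`` maps every observed level of ``clinical[row_var]`` to a
    collapsed level, or to ``None`` to exclude it (e.g. grade ``Gx``,
    response ``not_applicable``). Patients with levels not covered by the
    map raise an error; excluded patients are counted in ``n_excluded``.
    """
    levels = clinical[row_var].astype(str)
    unknown = set(levels.unique()) - set(collapse_map)
    if unknown:
        raise ValueError(f"collapse_map does not cover levels: {sorted(unknown)}")
    collapsed = levels.map(collapse_map)
    keep = collapsed.notna()
    n_excluded = int((~keep).sum())

    carrier = carrier.reindex(clinical.index).astype(bool)
    rows: list[str] = []
    for lvl in collapse_map.values():
        if lvl is not None and lvl not in rows:
            rows.append(lvl)
    counts = np.zeros((len(rows), 2), dtype=np.int64)
    for i, lvl in enumerate(rows):
        in_lvl = keep & (collapsed == lvl)
        counts[i, 0] = int((in_lvl & ~carrier).sum())
        counts[i, 1] = int((in_lvl & carrier).sum())
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty row level after collapse")
    return ContingencyTable(rows, list(carrier_labels), counts, n_excluded=n_excluded)


def fisher_exact_2x2(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability is at most that of the observed table.
    Degenerate margins (an empty row or column) return p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    a, b = int(counts[0, 0]), int(counts[0, 1])
    c, d = int(counts[1, 0]), int(counts[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _REL_EPS)].sum()))


def _table_log_prob(flat: np.ndarray, const: float) -> float:
    # log P(table | margins) under the multivariate hypergeometric null
    return const - sum(math.lgamma(x + 1) for x in flat)


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r = len(row_sums)

    def rows(i, remaining_cols):
        if i == r - 1:
            if all(v >= 0 for v in remaining_cols):
                yield (tuple(remaining_cols),)
            return
        for comp in _compositions(row_sums[i], remaining_cols):
            new_cols = [rc - x for rc, x in zip(remaining_cols, comp)]
            for rest in rows(i + 1, new_cols):
                yield (comp,) + rest

    yield from rows(0, list(col_sums))


def _compositions(total, caps):
    """Non-negative integer vectors summing to ``total`` with per-cell caps."""
    c = len(caps)

    def rec(j, left):
        if j == c - 1:
            if 0 <= left <= caps[j]:
                yield (left,)
            return
        lo = max(0, left - sum(caps[j + 1:]))
        for x in range(lo, min(caps[j], left) + 1):
            for rest in rec(j + 1, left - x):
                yield (x,) + rest

    yield from rec(0, total)


def _count_tables(row_sums, col_sums, budget):
    count = 0
    for _ in _enumerate_tables(row_sums, col_sums):
        count += 1
        if count > budget:
            return count
    return count


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray,
    *,
    budget: int = 2_000_000,
    monte_carlo: bool = False,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Freeman–Halton exact p-value for an r×c table.

    Enumerates every table consistent with the observed margins and sums
    the probabilities of those no more probable than the observed table.
    If the enumeration would exceed ``budget`` tables, raises unless
    ``monte_carlo`` is set, in which case tables are sampled from the
    margin-fixed null (seeded) and the add-one empirical p is returned.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    if n == 0 or (row_sums == 0).all() or (col_sums == 0).all():
        return 1.0
    # drop empty rows/columns: they do not change the null distribution
    counts = counts[row_sums > 0][:, col_sums > 0]
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        return 1.0

    const = (
        sum(math.lgamma(x + 1) for x in row_sums)
        + sum(math.lgamma(x + 1) for x in col_sums)
        - math.lgamma(n + 1)
    )
    logp_obs = _table_log_prob(counts.ravel(), const)

    if monte_carlo:
        rng = np.random.default_rng(seed)
        hits = 0
        dist = sps.random_table(row_sums, col_sums, seed=rng)
        sims = dist.rvs(n_sim, method="patefield")
        for t in sims:
            if _table_log_prob(np.asarray(t).ravel(), const) <= logp_obs + 1e-10:
                hits += 1
        return (1 + hits) / (n_sim + 1)

    if _count_tables(list(row_sums), list(col_sums), budget) > budget:
        raise ValueError(
            "table too large for exhaustive enumeration; "
            "call with monte_carlo=True and a seed"
        )
    total = 0.0
    thresh = logp_obs + abs(logp_obs) * _REL_EPS + 1e-12
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        flat = [x for row in t for x in row]
        lp = _table_log_prob(np.asarray(flat), const)
        if lp <= thresh:
            total += math.exp(lp)
    return float(min(1.0, total))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p (k−1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = sps.kruskal(*arrays)
    return float(stat), float(p)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approx p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def adjust_family(results: list[TestResult]) -> list[TestResult]:
    """Apply B-H across a family of TestResults, recording the family size."""
    if not results:
        return results
    adj = bh_adjust([r.p_crude for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.family_size = len(results)
    return results
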