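"""Three-phase in-silico gene prioritization for a targeted capture panel.

Candidate pharmacogenes are prioritized from a drug-sensitivity screen of
cell-line models and a human tumor mutation catalog:

* phase 1 — rank cell lines by drug sensitivity (IC50, AUC as tiebreaker),
  take the k most sensitive and k most resistant lines (with a quota of
  colorectal-origin lines per tail), and keep genes whose mutation count
  exceeds 5 % of a line's total mutations in at least half of the lines of
  a tail — excluding genes whose counts pile up in a single line;
* phase 2 — normalize gene symbols against an alias map (HGNC-style) and
  merge the sensitive/resistant candidates;
* phase 3 — cross-check against a tumor catalog, retaining genes mutated
  in more than 5 % of tumors and absent from the catalog's not-mutated
  list;
* assembly — union the core with oncodriver/actionable/extra enrichment
  lists, recording per-gene provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TumorCatalog",
    "PanelSelection",
    "rank_cell_lines",
    "phase1_select",
    "phase2_merge",
    "phase3_crosscheck",
    "assemble_panel",
    "design_panel",
]


@dataclass(frozen=True)
class TumorCatalog:
    """Tumor-cohort mutation catalog: per-gene mutated fraction + never-mutated list."""

    mutated_freq: dict[str, float]
    not_mutated: frozenset[str]

    def __post_init__(self) -> None:
        overlap = set(self.mutated_freq) & set(self.not_mutated)
        if overlap:
            raise ValueError(f"genes in both mutated_freq and not_mutated: {sorted(overlap)}")
        bad = {g: f for g, f in self.mutated_freq.items() if not 0 <= f <= 1}
        if bad:
            raise ValueError(f"frequencies outside [0,1]: {bad}")


@dataclass
class PanelSelection:
    phase1_sensitive: set[str]
    phase1_resistant: set[str]
    phase2_merged: set[str]
    phase3_core: set[str]
    enrichment: set[str]
    final_panel: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)


def rank_cell_lines(
    sensitivity: pd.DataFrame,
    drug: str,
    k: int,
    crc_quota: int,
) -> tuple[list[str], list[str]]:
    """The k most sensitive and k most resistant cell lines for a drug.

    ``sensitivity`` columns: ``cell_line_id, drug, ic50, auc, tissue``.
    Ordering is ascending IC50 for sensitivity, with AUC then
    ``cell_line_id`` breaking ties. Each tail contains exactly
    ``crc_quota`` CRC-origin lines: the quota is filled from the
    CRC-restricted ranking first, the remainder from the global ranking.
    """
    sub = sensitivity[sensitivity["drug"] == drug].copy()
    if sub["ic50"].isna().all():
        raise ValueError(f"no IC50 values for drug {drug!r}")
    sub = sub.dropna(subset=["ic50"])
    if len(sub) < 2 * k:
        raise ValueError(f"need at least {2 * k} lines with sensitivity for {drug!r}")
    sub = sub.sort_values(["ic50", "auc", "cell_line_id"], kind="stable")

    def _take_tail(ordered: pd.DataFrame) -> list[str]:
        crc = ordered[ordered["tissue"] == "CRC"]
        if len(crc) < crc_quota:
            raise ValueError(f"fewer than {crc_quota} CRC lines available for a tail")
        quota_ids = crc["cell_line_id"].head(crc_quota).tolist()
        rest = ordered[~ordered["cell_line_id"].isin(quota_ids)]
        fill = rest["cell_line_id"].head(k - crc_quota).tolist()
        return quota_ids + fill

    sensitive = _take_tail(sub)
    resistant = _take_tail(sub.iloc[::-1])
    if set(sensitive) & set(resistant):
        raise ValueError("sensitive and resistant tails overlap; too few lines")
    return sensitive, resistant


def phase1_select(
    mutations: pd.DataFrame,
    lines: list[str],
    share_threshold: float = 0.05,
    per_line: bool = True,
) -> set[str]:
    """Genes recurrently mutated across a tail of cell lines.

    ``mutations`` is long format: ``cell_line_id, gene, n_mutations``.
    With the default per-line rule, gene g is selected when, in at least
    ceil(|lines|/2) of the lines, g's mutation count strictly exceeds
    ``share_threshold`` of that line's total mutation count — excluding
    genes with many mutations concentrated in one line. The alternative
    (``per_line=False``) measures g's share of the tail-wide total.
    Lines with zero total mutations are excluded from the denominator
    count (logged).
    """
    if not lines:
        raise ValueError("empty cell-line category")
    sub = mutations[mutations["cell_line_id"].isin(lines)]
    totals = sub.groupby("cell_line_id")["n_mutations"].sum()
    zero = [ln for ln in lines if totals.get(ln, 0) == 0]
    if zero:
        logger.warning("excluding %d zero-mutation lines from phase 1: %s", len(zero), zero)
    active = [ln for ln in lines if ln not in zero]
    need = math.ceil(len(active) / 2)
    if not active:
        return set()
    if per_line:
        counts = sub.pivot_table(
            index="gene", columns="cell_line_id", values="n_mutations",
            aggfunc="sum", fill_value=0,
        ).reindex(columns=active, fill_value=0)
        share = counts / totals.reindex(active)
        hits = (share > share_threshold).sum(axis=1)
        return set(hits[hits >= need].index)
    grand = float(totals.reindex(active).sum())
    per_gene = sub[sub["cell_line_id"].isin(active)].groupby("gene")["n_mutations"].sum()
    return set(per_gene[per_gene / grand > share_threshold].index)


def phase2_merge(
    sensitive: set[str],
    resistant: set[str],
    alias_map: dict[str, str] | None = None,
) -> set[str]:
    """Normalize symbols via the alias map, then union the two candidate sets."""
    alias_map = alias_map or {}

    def norm(genes):
        out = set()
        for g in genes:
            if g in alias_map:
                out.add(alias_map[g])
            else:
                out.add(g)
        return out

    return norm(sensitive) | norm(resistant)


def phase3_crosscheck(
    merged: set[str],
    catalog: TumorCatalog,
    min_freq: float = 0.05,
) -> set[str]:
    """Retain genes mutated in tumors strictly above ``min_freq`` and not on
    the catalog's never-mutated list."""
    kept = set()
    for g in merged:
        if g in catalog.not_mutated:
            continue
        if catalog.mutated_freq.get(g, 0.0) > min_freq:
            kept.add(g)
    return kept


def assemble_panel(
    core: set[str],
    oncodrivers: set[str] = frozenset(),
    actionable: set[str] = frozenset(),
    extra: set[str] = frozenset(),
    phase1_sensitive: set[str] = frozenset(),
    phase1_resistant: set[str] = frozenset(),
    phase2_merged: set[str] = frozenset(),
) -> PanelSelection:
    """Union the core with enrichment lists, tracking per-gene provenance."""
    enrichment = set(oncodrivers) | set(actionable) | set(extra)
    final = set(core) | enrichment
    if not final:
        logger.warning("assembled panel is empty")
    provenance: dict[str, list[str]] = {}
    for name, genes in (
        ("core", core), ("oncodriver", oncodrivers),
        ("actionable", actionable), ("extra", extra),
    ):
        for g in genes:
            provenance.setdefault(g, []).append(name)
    return PanelSelection(
        phase1_sensitive=set(phase1_sensitive),
        phase1_resistant=set(phase1_resistant),
        phase2_merged=set(phase2_merged),
        phase3_core=set(core),
        enrichment=enrichment,
        final_panel=final,
        provenance=provenance,
    )


def design_panel(
    mutations: pd.DataFrame,
    sensitivity: pd.DataFrame,
    catalog: TumorCatalog,
    drugs: tuple[str, ...] = ("5FU", "oxaliplatin"),
    k: int = 20,
    crc_quota: int = 10,
    min_freq: float = 0.05,
    alias_map: dict[str, str] | None = None,
    enrichment: set[str] = frozenset(),
) -> PanelSelection:
    """End-to-end phases 1–3 plus assembly, run per drug and merged."""
    sens_all: set[str] = set()
    res_all: set[str] = set()
    for drug in drugs:
        sens_lines, res_lines = rank_cell_lines(sensitivity, drug, k, crc_quota)
        sens_all |= phase1_select(mutations, sens_lines)
        res_all |= phase1_select(mutations, res_lines)
    merged = phase2_merge(sens_all, res_all, alias_map)
    core = phase3_crosscheck(merged, catalog, min_freq)
    return assemble_panel(
        core, extra=set(enrichment),
        phase1_sensitive=sens_all, phase1_resistant=res_all, phase2_merged=merged,
    )
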