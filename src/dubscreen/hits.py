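"""Two-tier gene-level hit calling.

Tier 1 (statistical gate, per hairpin): a hairpin is flagged depleted or
enriched when |log2 fold change| >= 1, BH-adjusted p <= 0.02 and average
abundance > 2.5 (log2-CPM scale) in the moderated-t table.

Tier 2 (magnitude gate + consolidation, per gene): a gene is a per-screen
dropout (resp. enrichment) when at least two of its hairpins are flagged and
each of those also shows a >= 10-fold median change across recipient mice
relative to T0. A gene with qualifying hairpins in both directions is
excluded outright. Consolidated hits must recur in at least two independent
screens; an exclusion in any screen dominates.

Both gates are applied conjunctively per hairpin — the statistical thresholds
and the stringent 10-fold-median criterion each have to hold. Per-mouse fold
changes are pseudocounted CPM ratios sample/T0 with the median taken across
mice; ``median_of="fold_changes"`` (default) can be switched to
``median_of="counts"`` to instead take the fold change of median abundances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import CountMatrix

__all__ = [
    "HitRuleConfig",
    "flag_hairpin",
    "flag_table",
    "median_fold_change",
    "per_mouse_fold_changes",
    "call_genes_screen",
    "consolidate_screens",
]

HAIRPIN_FLAGS = ("depleted", "enriched", "ns")
SCREEN_VERDICTS = ("dropout", "enriched", "excluded_opposite", "not_hit", "untested")
CONSOLIDATED = ("dropout_hit", "enriched_hit", "excluded", "not_hit")


@dataclass(frozen=True)
class HitRuleConfig:
    logfc_min: float = 1.0
    adj_p_max: float = 0.02
    ave_abund_min: float = 2.5
    fold_median_min: float = 10.0  # linear scale
    min_shrnas: int = 2
    min_screens: int = 2
    median_of: str = "fold_changes"  # or "counts"

    def __post_init__(self):
        if min(self.logfc_min, self.adj_p_max, self.ave_abund_min, self.fold_median_min) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_shrnas < 1 or self.min_screens < 1:
            raise ValueError("min_shrnas and min_screens must be >= 1")
        if self.median_of not in ("fold_changes", "counts"):
            raise ValueError("median_of must be 'fold_changes' or 'counts'")


def flag_hairpin(row, cfg: HitRuleConfig = HitRuleConfig()) -> str:
    """Statistical flag for one differential-table row: 'depleted',
    'enriched' or 'ns'."""
    log_fc, adj_p, ave = row["log_fc"], row["adj_p"], row["ave_abund"]
    if any(pd.isna(v) for v in (log_fc, adj_p, ave)):
        return "ns"
    if adj_p <= cfg.adj_p_max and ave > cfg.ave_abund_min:
        if log_fc <= -cfg.logfc_min:
            return "depleted"
        if log_fc >= cfg.logfc_min:
            return "enriched"
    return "ns"


def flag_table(diff: pd.DataFrame, cfg: HitRuleConfig = HitRuleConfig()) -> pd.Series:
    return diff.apply(flag_hairpin, axis=1, cfg=cfg).rename("flag")


def median_fold_change(per_mouse_fc) -> float:
    """Median of per-mouse linear fold changes (midpoint of the middle pair
    for even n)."""
    fc = np.asarray(list(per_mouse_fc), dtype=float)
    if fc.size == 0:
        raise ValueError("empty fold-change list")
    return float(np.median(fc))


def per_mouse_fold_changes(
    cm: CountMatrix,
    screen_id: str,
    tissue: str = "BM",
    pseudocount: float = 0.5,
    samples: list | None = None,
) -> pd.DataFrame:
    """Linear per-mouse fold change of each hairpin vs the screen's T0, on
    pseudocounted CPM: FC = CPM_mouse / CPM_T0. Columns are mouse samples."""
    from .stats import normalize_log_cpm

    sheet = cm.sheet
    ref = sheet.reference_sample(screen_id)
    test = samples if samples is not None else sheet.samples(screen_id, tissue)
    if not test:
        raise ValueError(f"screen {screen_id!r} has no {tissue!r} samples")
    log_cpm = normalize_log_cpm(
        CountMatrix(cm.counts[test + [ref]], cm.unassigned.reindex(test + [ref]), sheet),
        pseudocount,
    )
    fc = np.power(2.0, log_cpm[test].sub(log_cpm[ref], axis=0))
    return fc


def call_genes_screen(
    flags: pd.Series,
    median_fc: pd.Series,
    gene_of: dict,
    cfg: HitRuleConfig = HitRuleConfig(),
    all_genes: list | None = None,
):
    """Per-screen gene verdicts from hairpin flags and median fold changes.

    A hairpin "qualifies" for dropout when flagged depleted AND its median FC
    <= 1/fold_median_min (symmetric for enrichment). Verdicts: 'dropout' /
    'enriched' (>= min_shrnas qualifying hairpins), 'excluded_opposite'
    (qualifying hairpins in both directions), 'untested' (no tested hairpin),
    else 'not_hit'. Returns ``(verdicts: Series, evidence: DataFrame)``.
    """
    orphans = [h for h in flags.index if h not in gene_of]
    if orphans:
        raise ValueError(f"hairpins without gene mapping: {orphans[:5]}")
    ev_rows = []
    per_gene: dict = {}
    for h in flags.index:
        g = gene_of[h]
        d = per_gene.setdefault(g, {"dropout": [], "enriched": [], "tested": 0})
        flag = flags[h]
        fc = median_fc.get(h, np.nan)
        if flag != "ns" or not pd.isna(fc):
            d["tested"] += 1
        qual = None
        if flag == "depleted" and fc <= 1.0 / cfg.fold_median_min:
            qual = "dropout"
        elif flag == "enriched" and fc >= cfg.fold_median_min:
            qual = "enriched"
        if qual:
            d[qual].append(h)
            ev_rows.append(
                {"gene_symbol": g, "hairpin_id": h, "direction": qual,
                 "median_fc": fc}
            )
    genes = all_genes if all_genes is not None else sorted(per_gene)
    verdicts = {}
    for g in genes:
        d = per_gene.get(g)
        if d is None or d["tested"] == 0:
            verdicts[g] = "untested"
            continue
        has_drop = len(d["dropout"]) >= 1
        has_enr = len(d["enriched"]) >= 1
        if has_drop and has_enr:
            verdicts[g] = "excluded_opposite"
        elif len(d["dropout"]) >= cfg.min_shrnas:
            verdicts[g] = "dropout"
        elif len(d["enriched"]) >= cfg.min_shrnas:
            verdicts[g] = "enriched"
        else:
            verdicts[g] = "not_hit"
    evidence = pd.DataFrame(
        ev_rows, columns=["gene_symbol", "hairpin_id", "direction", "median_fc"]
    )
    return pd.Series(verdicts, name="verdict"), evidence


def consolidate_screens(
    per_screen: dict,
    cfg: HitRuleConfig = HitRuleConfig(),
):
    """Consolidate per-screen gene verdicts across independent screens.

    ``per_screen`` maps screen_id -> verdict Series (from
    :func:`call_genes_screen`). A gene is a consolidated dropout_hit
    (enriched_hit) when >= min_screens screens agree on that verdict; any
    excluded_opposite verdict dominates; genes untested everywhere stay out
    of the hit set. Returns ``(calls: DataFrame, overlap: DataFrame)`` where
    ``overlap`` counts hit genes per exact screen combination (Venn cells),
    per direction.
    """
    screens = list(per_screen)
    if len(screens) != len(set(screens)):
        raise ValueError("duplicate screen ids")
    if len(screens) < 2:
        raise ValueError("need >= 2 screens to consolidate")
    genes = sorted(set().union(*[set(v.index) for v in per_screen.values()]))
    rows = []
    for g in genes:
        vs = {s: per_screen[s].get(g, "untested") for s in screens}
        n_drop = sum(v == "dropout" for v in vs.values())
        n_enr = sum(v == "enriched" for v in vs.values())
        if any(v == "excluded_opposite" for v in vs.values()) or (n_drop and n_enr):
            call = "excluded"
        elif n_drop >= cfg.min_screens:
            call = "dropout_hit"
        elif n_enr >= cfg.min_screens:
            call = "enriched_hit"
        else:
            call = "not_hit"
        rows.append({"gene_symbol": g, **{f"screen_{s}": vs[s] for s in screens},
                     "consolidated": call})
    calls = pd.DataFrame(rows).set_index("gene_symbol")

    overlap_rows = []
    for direction, verdict in (("dropout", "dropout"), ("enriched", "enriched")):
        hit_sets = {s: {g for g in genes if per_screen[s].get(g) == verdict}
                    for s in screens}
        for r in range(1, len(screens) + 1):
            for combo in itertools.combinations(screens, r):
                inside = set.intersection(*[hit_sets[s] for s in combo])
                outside = set().union(*[hit_sets[s] for s in screens if s not in combo]) \
                    if len(combo) < len(screens) else set()
                overlap_rows.append(
                    {
                        "direction": direction,
                        "screens": "+".join(combo),
                        "n_genes": len(inside - outside),
                    }
                )
    overlap = pd.DataFrame(overlap_rows, columns=["direction", "screens", "n_genes"])
    return calls, overlap
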