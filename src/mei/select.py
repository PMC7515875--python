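"""Differential gene selection from the six MEI measures.

The standard criterion keeps genes with a significant exon change
(E_p < 0.001) *and* a twofold mean change.  The expanded MEI criterion
keeps genes that pass the same E_p gate together with at least one of:
twofold mean change (E_m), significant intron change (I_p < 0.001),
significant exon:intron correlation differential (C_d < 0.005), or a
twofold change in exon or intron Gini (G_e, G_i).  Fold-type thresholds
are direction-agnostic: max(x, 1/x) >= threshold, so both gains and
losses of expression or variability qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust

__all__ = [
    "SelectionConfig",
    "MEIRecord",
    "evaluate_gene",
    "fdr_threshold_check",
    "build_report",
    "SelectionReport",
]

FLAG_NAMES = ("Ep", "Em", "Ip", "Cd", "Ge", "Gi")
SECONDARY_FLAGS = ("Em", "Ip", "Cd", "Ge", "Gi")


@dataclass
class SelectionConfig:
    """Thresholds for the standard and MEI selection criteria."""

    ep_alpha: float = 0.001
    ip_alpha: float = 0.001
    cd_alpha: float = 0.005
    fold_min: float = 2.0
    gini_fold_min: float = 2.0
    fdr_target: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ep_alpha", "ip_alpha", "cd_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fold_min <= 1 or self.gini_fold_min <= 1:
            raise ValueError("fold thresholds must exceed 1")


@dataclass
class MEIRecord:
    """Per-gene bundle of the six differential measures.

    Undefined measures (e.g. a Gini ratio when the control Gini is zero)
    are NaN; their flags evaluate to False and the gene is listed as not
    evaluable for that measure.
    """

    gene_id: str
    E_p: float
    E_m: float
    I_p: float
    C_d: float
    G_e: float
    G_i: float
    flags: set[str] = field(default_factory=set)
    standard_hit: bool = False
    mei_hit: bool = False


def _fold_flag(value: float, threshold: float) -> bool:
    if not np.isfinite(value) or value <= 0:
        return False
    return max(value, 1.0 / value) >= threshold


def _p_flag(value: float, alpha: float) -> bool:
    return bool(np.isfinite(value) and value < alpha)


def evaluate_gene(
    rec: MEIRecord, cfg: SelectionConfig
) -> tuple[set[str], bool, bool]:
    """Evaluate one gene's flags and the standard / MEI hit status.

    standard_hit = Ep and Em; mei_hit = Ep and any secondary flag.
    The record is updated in place and the triple returned.
    """
    flags = set()
    if _p_flag(rec.E_p, cfg.ep_alpha):
        flags.add("Ep")
    if _fold_flag(rec.E_m, cfg.fold_min):
        flags.add("Em")
    if _p_flag(rec.I_p, cfg.ip_alpha):
        flags.add("Ip")
    if _p_flag(rec.C_d, cfg.cd_alpha):
        flags.add("Cd")
    if _fold_flag(rec.G_e, cfg.gini_fold_min):
        flags.add("Ge")
    if _fold_flag(rec.G_i, cfg.gini_fold_min):
        flags.add("Gi")
    standard = "Ep" in flags and "Em" in flags
    mei = "Ep" in flags and any(f in flags for f in SECONDARY_FLAGS)
    rec.flags = flags
    rec.standard_hit = standard
    rec.mei_hit = mei
    return flags, standard, mei


def fdr_threshold_check(
    exon_p: np.ndarray, intron_p: np.ndarray, fdr_target: float = 0.1
) -> float:
    """Largest p threshold honoured by BH at ``fdr_target`` on both vectors.

    For each vector, Benjamini-Hochberg at level ``fdr_target`` admits all
    p at or below its step-up cutoff; the diagnostic returned is the
    smaller of the two cutoffs (0 when nothing passes), to be read beside
    the configured ``ep_alpha``.
    """

    def bh_cutoff(p: np.ndarray) -> float:
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValueError("empty p-vector")
        q = bh_adjust(p)
        passed = p[q <= fdr_target]
        return float(passed.max()) if passed.size else 0.0

    return min(bh_cutoff(exon_p), bh_cutoff(intron_p))


@dataclass
class SelectionReport:
    table: pd.DataFrame  # one row per gene, sorted by priority
    summary: pd.DataFrame  # counts per flag combination
    n_standard: int
    n_mei: int
    watch_list: list[str]  # secondary-only genes failing the Ep gate


def build_report(records: list[MEIRecord], cfg: SelectionConfig) -> SelectionReport:
    """Evaluate all genes and assemble the annotated, prioritised report.

    Genes are sorted by number of satisfied criteria (descending), then by
    E_p (ascending), so genes hit by every measure lead the list.  Genes
    with secondary evidence but no significant exon change go to a watch
    list rather than being counted as hits.
    """
    rows = []
    watch = []
    for rec in records:
        flags, standard, mei = evaluate_gene(rec, cfg)
        if not standard and not mei and any(f in flags for f in SECONDARY_FLAGS):
            watch.append(rec.gene_id)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "E_p": rec.E_p,
                "E_m": rec.E_m,
                "I_p": rec.I_p,
                "C_d": rec.C_d,
                "G_e": rec.G_e,
                "G_i": rec.G_i,
                **{f: (f in flags) for f in FLAG_NAMES},
                "n_flags": len(flags),
                "standard_hit": standard,
                "mei_hit": mei,
            }
        )
    if not rows:
        empty = pd.DataFrame(
            columns=["gene_id", "E_p", "E_m", "I_p", "C_d", "G_e", "G_i",
                     *FLAG_NAMES, "n_flags", "standard_hit", "mei_hit"]
        )
        return SelectionReport(empty, pd.DataFrame(columns=["combination", "count"]),
                               0, 0, [])
    table = pd.DataFrame(rows).sort_values(
        ["n_flags", "E_p"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    combo = table[list(FLAG_NAMES)].apply(
        lambda r: "+".join([f for f in FLAG_NAMES if r[f]]) or "none", axis=1
    )
    summary = (
        combo.value_counts().rename_axis("combination").reset_index(name="count")
    )
    return SelectionReport(
        table=table,
        summary=summary,
        n_standard=int(table["standard_hit"].sum()),
        n_mei=int(table["mei_hit"].sum()),
        watch_list=sorted(watch),
    )
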