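"""End-to-end MEI analysis: matched counts -> six measures -> gene report.

Given calibrated matched exon/intron counts and a two-group sample sheet,
compute for every gene the exon and intron negative binomial p-values,
the exon fold change, the case/control exon and intron Gini ratios and
the Fisher correlation-differential p-value, then apply the standard and
expanded MEI selection criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodel import MatchedCounts
from .select import MEIRecord, SelectionConfig, SelectionReport, build_report, fdr_threshold_check
from .stats import (
    bh_adjust,
    correlation_differential,
    delta_gini,
    exon_intron_correlation,
    gini_unbiased,
    nb_test,
)

__all__ = ["MEIResult", "compute_mei_records", "run_mei", "read_sample_sheet"]

CONDITIONS = ("control", "case")
MIN_GROUP_N = 4  # Fisher z needs n >= 4 per group


def read_sample_sheet(path) -> pd.Series:
    """Read a two-column TSV sample sheet (sample_id, condition)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cond = df.iloc[:, 0].astype(str)
    bad = set(cond) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    return cond


def _split_groups(mc: MatchedCounts, sheet: pd.Series):
    missing = mc.samples.difference(sheet.index)
    if len(missing):
        raise ValueError(f"samples without condition: {missing.tolist()}")
    control = [s for s in mc.samples if sheet[s] == "control"]
    case = [s for s in mc.samples if sheet[s] == "case"]
    if len(control) < MIN_GROUP_N or len(case) < MIN_GROUP_N:
        raise ValueError(
            f"each condition needs >= {MIN_GROUP_N} samples "
            f"(got {len(control)} control, {len(case)} case)"
        )
    return control, case


@dataclass
class MEIResult:
    records: list[MEIRecord]
    measures: pd.DataFrame  # tidy per-gene table incl. q-values and correlations
    report: SelectionReport
    bh_threshold: float  # diagnostic: BH cutoff honoured by both p vectors


def compute_mei_records(
    mc: MatchedCounts, sheet: pd.Series
) -> tuple[list[MEIRecord], pd.DataFrame]:
    """Compute the six MEI measures for every gene.

    Returns the record list plus a tidy DataFrame that also carries the
    group means, dispersions, per-group correlations and BH q-values.
    """
    control, case = _split_groups(mc, sheet)
    ex_c = mc.exon[control].to_numpy(dtype=float)
    ex_t = mc.exon[case].to_numpy(dtype=float)
    in_c = mc.intron[control].to_numpy(dtype=float)
    in_t = mc.intron[case].to_numpy(dtype=float)
    n_c, n_t = len(control), len(case)

    rows = []
    for i, gene in enumerate(mc.genes):
        ex_test = nb_test(ex_c[i], ex_t[i], gene_id=gene, region_type="exon")
        in_test = nb_test(in_c[i], in_t[i], gene_id=gene, region_type="intron")
        g_ec = gini_unbiased(ex_c[i]) if n_c >= 2 else np.nan
        g_et = gini_unbiased(ex_t[i])
        g_ic = gini_unbiased(in_c[i])
        g_it = gini_unbiased(in_t[i])
        _, ge_ratio = delta_gini(g_ec, g_et)
        _, gi_ratio = delta_gini(g_ic, g_it)
        r_c = exon_intron_correlation(ex_c[i], in_c[i]) if n_c >= 4 else np.nan
        r_t = exon_intron_correlation(ex_t[i], in_t[i]) if n_t >= 4 else np.nan
        cd = correlation_differential(r_c, n_c, r_t, n_t, gene_id=gene)
        rows.append(
            {
                "gene_id": gene,
                "E_p": ex_test.p_value,
                "E_m": ex_test.fold_change,
                "I_p": in_test.p_value,
                "C_d": cd.p_value,
                "G_e": ge_ratio,
                "G_i": gi_ratio,
                "exon_mean_control": ex_test.mean_control,
                "exon_mean_case": ex_test.mean_case,
                "intron_mean_control": in_test.mean_control,
                "intron_mean_case": in_test.mean_case,
                "exon_dispersion": ex_test.dispersion,
                "intron_dispersion": in_test.dispersion,
                "gini_exon_control": g_ec,
                "gini_exon_case": g_et,
                "gini_intron_control": g_ic,
                "gini_intron_case": g_it,
                "r_control": r_c,
                "r_case": r_t,
            }
        )
    measures = pd.DataFrame(rows)
    measures["E_q"] = bh_adjust(measures["E_p"].to_numpy())
    measures["I_q"] = bh_adjust(measures["I_p"].to_numpy())
    records = [
        MEIRecord(
            gene_id=r.gene_id, E_p=r.E_p, E_m=r.E_m, I_p=r.I_p,
            C_d=r.C_d, G_e=r.G_e, G_i=r.G_i,
        )
        for r in measures.itertuples(index=False)
    ]
    return records, measures


def run_mei(
    mc: MatchedCounts, sheet: pd.Series, cfg: SelectionConfig | None = None
) -> MEIResult:
    """Full analysis: measures, selection report and the BH diagnostic."""
    cfg = cfg or SelectionConfig()
    records, measures = compute_mei_records(mc, sheet)
    report = build_report(records, cfg)
    bh_t = fdr_threshold_check(
        measures["E_p"].to_numpy(), measures["I_p"].to_numpy(), cfg.fdr_target
    )
    return MEIResult(records=records, measures=measures, report=report, bh_threshold=bh_t)
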