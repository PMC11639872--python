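"""Frontloading classification and SRG expression-distribution summaries.

A gene is *frontloaded* when its constitutive (control, 28 degC) expression
sits above the transcriptome-wide median and its expression barely moves
under heat: normalized basal counts strictly above the median AND
|log2FC| strictly below 2 in the heated treatment (at both timepoints by
default).  The complementary *low-basal responsive* pattern — basal at or
below the median with significant upregulation under heat — marks species
that mount an inducible rather than a constitutive stress response.

Basal expression defaults to the mean CPM over all control libraries (both
timepoints); the unit is switchable (cpm | tpm | vst).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_data import SampleMetadata
from .diffexpr import bh_adjust

LFC_FRONT_DEFAULT = 2.0

__all__ = [
    "basal_expression",
    "classify_frontloaded",
    "frontloading_calls",
    "srg_expression_summary",
    "responsive_srg_summary",
    "frontloading_report",
]


def basal_expression(expr_matrix: pd.DataFrame, meta: SampleMetadata) -> pd.Series:
    """Per-gene mean expression over all control libraries (both timepoints)."""
    ctrl = [s for s in meta.samples_where(treatment="control") if s in expr_matrix.columns]
    if not ctrl:
        raise ValueError("no control samples in expression matrix")
    return expr_matrix[ctrl].mean(axis=1).rename("basal")


def classify_frontloaded(
    basal,
    median: float,
    log2fc_4h,
    log2fc_24h,
    lfc_bound: float = LFC_FRONT_DEFAULT,
    timepoint_rule: str = "both",
):
    """Frontloading rule: basal > median (strict) and |log2FC| < bound (strict).

    ``timepoint_rule="both"`` requires stability at 4 h and 24 h;
    ``"either"`` accepts stability at one timepoint.
    """
    b = np.asarray(basal, dtype=float)
    f4 = np.abs(np.asarray(log2fc_4h, dtype=float))
    f24 = np.abs(np.asarray(log2fc_24h, dtype=float))
    if timepoint_rule == "both":
        stable = (f4 < lfc_bound) & (f24 < lfc_bound)
    elif timepoint_rule == "either":
        stable = (f4 < lfc_bound) | (f24 < lfc_bound)
    else:
        raise ValueError("timepoint_rule must be 'both' or 'either'")
    out = (b > median) & stable
    if np.isscalar(basal):
        return bool(out)
    if isinstance(basal, pd.Series):
        return pd.Series(out, index=basal.index, name="frontloaded")
    return out


def frontloading_calls(
    expr_matrix: pd.DataFrame,
    meta: SampleMetadata,
    de_results: pd.DataFrame,
    lfc_bound: float = LFC_FRONT_DEFAULT,
    timepoint_rule: str = "both",
) -> pd.DataFrame:
    """Per-gene frontloading / low-basal-responsive calls.

    ``de_results`` stacks per-timepoint DE frames (gene_id index, columns
    log2fc, status, timepoint_h).  Genes absent from a timepoint's DE frame
    (filtered) are treated as unchanged (log2FC 0, status ns).  The two flags
    are mutually exclusive by construction (basal above vs at-or-below the
    median).
    """
    basal = basal_expression(expr_matrix, meta)
    median = float(basal.median())
    per_tp = {}
    status_up = pd.Series(False, index=basal.index)
    for tp, sub in de_results.groupby("timepoint_h"):
        sub = sub[~sub.index.duplicated()]
        per_tp[int(tp)] = sub["log2fc"].reindex(basal.index).fillna(0.0)
        status_up |= (sub["status"] == "up").reindex(basal.index, fill_value=False)
    lfc4 = per_tp.get(4, pd.Series(0.0, index=basal.index))
    lfc24 = per_tp.get(24, pd.Series(0.0, index=basal.index))
    front = classify_frontloaded(basal, median, lfc4, lfc24, lfc_bound, timepoint_rule)
    out = pd.DataFrame(
        {
            "basal_expr": basal,
            "transcriptome_median": median,
            "log2fc_4h": lfc4,
            "log2fc_24h": lfc24,
            "frontloaded": front,
            "low_basal_responsive": (basal <= median) & status_up,
        }
    )
    out.index.name = "gene_id"
    return out


def srg_expression_summary(
    expr_matrix: pd.DataFrame,
    catalog: pd.DataFrame,
    meta: SampleMetadata,
    de_results: pd.DataFrame,
) -> dict:
    """Distribution summary of SRG vs all-gene basal expression.

    Returns the all-gene and SRG basal medians, the number of SRGs above and
    below the transcriptome median, and the mean |log2FC| over SRGs per
    timepoint.
    """
    if catalog.empty:
        raise ValueError("empty SRG catalog")
    basal = basal_expression(expr_matrix, meta)
    srg_genes = basal.index.intersection(catalog.index)
    median_all = float(basal.median())
    srg_basal = basal.loc[srg_genes]
    mean_abs_lfc = {}
    for tp, sub in de_results.groupby("timepoint_h"):
        lfc = sub["log2fc"].reindex(srg_genes).fillna(0.0)
        mean_abs_lfc[int(tp)] = float(lfc.abs().mean())
    return {
        "median_all": median_all,
        "median_srg": float(srg_basal.median()),
        "n_srg": int(len(srg_genes)),
        "n_srg_above_median": int((srg_basal > median_all).sum()),
        "n_srg_below_median": int((srg_basal <= median_all).sum()),
        "mean_abs_log2fc": mean_abs_lfc,
    }


def responsive_srg_summary(
    calls: pd.DataFrame,
    de_results: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
) -> dict:
    """Summaries for low-basal SRGs (basal <= transcriptome median).

    Mean |log2FC| per timepoint over the low-basal set, plus — for the subset
    additionally called up at a timepoint — mean log2FC per timepoint and per
    SRG family.  Empty subsets yield empty summaries, never errors.
    """
    if catalog is not None:
        calls = calls.loc[calls.index.intersection(catalog.index)]
    low = calls[calls["basal_expr"] <= calls["transcriptome_median"]]
    out: dict = {"n_low_basal": int(low.shape[0]), "mean_abs_log2fc": {}, "upregulated": {}}
    if low.empty:
        return out
    for tp, col in ((4, "log2fc_4h"), (24, "log2fc_24h")):
        out["mean_abs_log2fc"][tp] = float(low[col].abs().mean())
    for tp in sorted(de_results["timepoint_h"].unique()):
        sub = de_results[de_results["timepoint_h"] == tp]
        up = sub.index[sub["status"] == "up"].intersection(low.index)
        entry: dict = {"n_up": int(len(up))}
        if len(up):
            entry["mean_log2fc"] = float(sub.loc[up, "log2fc"].mean())
            if catalog is not None:
                entry["by_family"] = (
                    sub.loc[up, "log2fc"]
                    .groupby(catalog["family"].reindex(up))
                    .mean()
                    .to_dict()
                )
        out["upregulated"][int(tp)] = entry
    return out


def frontloading_report(
    calls: pd.DataFrame,
    catalog: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-family frontloaded counts with hypergeometric enrichment flags.

    Enrichment asks whether a family holds more frontloaded genes than
    expected given the family's size and the overall frontloaded fraction
    (one-sided hypergeometric over all genes with calls), BH-adjusted across
    families.
    """
    genes = calls.index
    fams = catalog["family"].reindex(genes).dropna()
    n_total = int(len(genes))
    n_front_total = int(calls["frontloaded"].sum())
    rows = []
    for family, members in fams.groupby(fams):
        idx = members.index
        k = int(calls.loc[idx, "frontloaded"].sum())
        n_fam = int(len(idx))
        p = float(hypergeom.sf(k - 1, n_total, n_front_total, n_fam)) if k > 0 else 1.0
        rows.append(
            {
                "family": family,
                "n_genes": n_fam,
                "n_frontloaded": k,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["family", "n_genes", "n_frontloaded", "pvalue", "qvalue", "enriched"]
        )
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    out["enriched"] = (out["qvalue"] < q_max) & (out["n_frontloaded"] > 0)
    return out
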