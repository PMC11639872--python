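"""Stress-response-gene (SRG) cataloguing and cross-species comparisons.

SRGs are identified by characteristic protein domains: a gene joins a family
when it carries at least one of the family's defining Pfam accessions at or
below the domain e-value cutoff.  A gene maps to at most one family —
first match in family-definition file order wins (logged).  Family
abundances are expressed relative to the total number of predicted peptides
per species; group differences (e.g. Robusta vs Complexa superfamilies) are
screened with an ordinary least-squares model on log relative abundance with
Benjamini-Hochberg correction, mirroring the linear-model-on-transformed-
abundance approach of microbiome association tools.  Orthogroup gene-count
profiles between species are compared by Pearson correlation.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

EVALUE_MAX_DEFAULT = 1e-5
Q_THRESHOLD_DEFAULT = 0.25

__all__ = [
    "assign_srg_families",
    "srg_relative_abundance",
    "group_association",
    "orthogroup_correlation",
]


def assign_srg_families(
    domains: pd.DataFrame,
    families: pd.DataFrame,
    evalue_max: float = EVALUE_MAX_DEFAULT,
) -> pd.DataFrame:
    """Map genes to SRG families by defining domains.

    ``domains``: gene_id, accession, evalue.  ``families``: family, category,
    accessions (tuple) — row order is priority.  Returns a catalog with one
    row per assigned gene (gene_id index; family, category columns).
    """
    if families.empty:
        raise ValueError("empty SRG family definition table")
    for _, fam in families.iterrows():
        bad = [a for a in fam["accessions"] if not str(a).upper().startswith("PF")]
        if bad:
            logger.warning(
                "family %s has non-Pfam-style accession(s): %s", fam["family"], bad
            )
    sig = domains[domains["evalue"] <= evalue_max]
    acc2fam: dict[str, tuple[int, str, str]] = {}
    for prio, (_, fam) in enumerate(families.iterrows()):
        for acc in fam["accessions"]:
            acc2fam.setdefault(acc, (prio, fam["family"], fam["category"]))
    matched = sig[sig["accession"].isin(acc2fam)]
    if matched.empty:
        return pd.DataFrame(columns=["family", "category"]).rename_axis("gene_id")
    rows = matched.assign(
        _prio=matched["accession"].map(lambda a: acc2fam[a][0]),
        family=matched["accession"].map(lambda a: acc2fam[a][1]),
        category=matched["accession"].map(lambda a: acc2fam[a][2]),
    )
    multi = rows.groupby("gene_id")["family"].nunique()
    if (multi > 1).any():
        logger.info(
            "%d gene(s) match multiple SRG families; keeping first by file order",
            int((multi > 1).sum()),
        )
    best = rows.sort_values(["gene_id", "_prio"], kind="stable").groupby(
        "gene_id", sort=True
    ).head(1)
    return best.set_index("gene_id")[["family", "category"]]


def srg_relative_abundance(
    catalogs: Mapping[str, pd.DataFrame],
    total_peptides: Mapping[str, int],
) -> pd.DataFrame:
    """Per-species per-family member counts relative to total peptides.

    ``catalogs`` maps species -> catalog (as from :func:`assign_srg_families`);
    ``total_peptides`` maps species -> total predicted peptide count.
    Returns a tidy frame (species, family, category, n_genes, fraction).
    """
    for species in catalogs:
        if int(total_peptides[species]) <= 0:
            raise ValueError(f"total peptides must be positive for {species}")
    records = []
    non_empty = [c[["family", "category"]] for c in catalogs.values() if not c.empty]
    families = (
        pd.concat(non_empty).drop_duplicates("family")
        if non_empty
        else pd.DataFrame(columns=["family", "category"])
    )
    for species, catalog in catalogs.items():
        total = int(total_peptides[species])
        counts = catalog["family"].value_counts()
        for _, fam in families.iterrows():
            n = int(counts.get(fam["family"], 0))
            records.append(
                {
                    "species": species,
                    "family": fam["family"],
                    "category": fam["category"],
                    "n_genes": n,
                    "fraction": n / total,
                }
            )
    return pd.DataFrame(records)


def group_association(
    abundances: pd.DataFrame,
    groups: Mapping[str, str],
    q_threshold: float = Q_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Screen families whose relative abundance separates species groups.

    Per family, OLS of log(fraction + half-minimum-positive pseudocount) on a
    two-level group indicator; BH adjustment across families.  Families with
    zero variance are flagged ``not_testable``.  Returns effect (log
    difference, group B minus group A), p, q, and a significance flag at
    ``q_threshold``.
    """
    ab = abundances.assign(group=abundances["species"].map(groups))
    if ab["group"].isna().any():
        missing = sorted(ab.loc[ab["group"].isna(), "species"].unique())
        raise ValueError(f"species without group label: {missing}")
    levels = sorted(ab["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    positive = ab.loc[ab["fraction"] > 0, "fraction"]
    pseudo = positive.min() / 2.0 if not positive.empty else 1e-9
    rows = []
    for family, sub in ab.groupby("family", sort=True):
        y = np.log(sub["fraction"] + pseudo)
        x = (sub["group"] == levels[1]).astype(float)
        n_per = sub.groupby("group")["species"].nunique()
        if y.nunique() == 1 or (n_per < 2).any():
            rows.append(
                {
                    "family": family,
                    "effect": float(y[x == 1].mean() - y[x == 0].mean())
                    if (x == 1).any() and (x == 0).any()
                    else np.nan,
                    "pvalue": np.nan,
                    "not_testable": True,
                }
            )
            continue
        model = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        rows.append(
            {
                "family": family,
                "effect": float(model.params[1]),
                "pvalue": float(model.pvalues[1]),
                "not_testable": False,
            }
        )
    out = pd.DataFrame(rows)
    testable = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if testable.any():
        out.loc[testable, "qvalue"] = bh_adjust(out.loc[testable, "pvalue"].to_numpy())
    out["significant"] = out["qvalue"] < q_threshold
    out.attrs["groups"] = {"reference": levels[0], "contrast": levels[1]}
    return out


def orthogroup_correlation(orthogroup_counts: pd.DataFrame) -> pd.DataFrame:
    """Species x species Pearson correlation of orthogroup gene-count profiles.

    Zero-variance species vectors yield missing correlations (diagonal stays
    1).  The matrix is symmetric with unit diagonal.
    """
    if orthogroup_counts.shape[0] < 2:
        raise ValueError("need at least two orthogroups")
    corr = orthogroup_counts.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr
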