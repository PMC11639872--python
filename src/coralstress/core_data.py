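"""Tabular data model and validated readers/writers.

Every table the pipeline touches is tab-delimited UTF-8 text with ``#``
comment lines ignored, matching the conventions of RSEM / OrthoFinder style
outputs.  The central object is the :class:`CountMatrix` — a non-negative
integer gene x sample table — accompanied by a per-sample design table
(:class:`SampleMetadata`), BLAST tabular hit tables, protein-domain
annotation tables, stress-response-gene (SRG) family definitions, and
orthogroup gene-count tables.

Readers validate invariants up front and fail loudly with the offending
identifier or line; they never silently drop rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "heated")

#: 12-column BLAST tabular (outfmt 6) header, plus an optional 13th taxon column.
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class DataValidationError(ValueError):
    """An input table violates a structural invariant."""


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: no data rows")
    return df


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample expression matrix.

    ``counts`` is indexed by gene id with one column per sample id.  Gene and
    sample ids are opaque strings (no Trinity isoform-name parsing happens
    here).  Library sizes (column sums) must be positive.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dup[:5]}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dup[:5]}")
        if c.isna().any().any():
            raise DataValidationError("count matrix contains missing values")
        if (c.to_numpy() < 0).any():
            bad = c.index[(c < 0).any(axis=1)][0]
            raise DataValidationError(f"negative count for gene {bad!r}")
        if not np.issubdtype(c.to_numpy().dtype, np.integer):
            arr = c.to_numpy()
            if not np.allclose(arr, np.rint(arr)):
                logger.warning(
                    "non-integer counts rounded half-to-even on ingest "
                    "(RSEM expected counts)"
                )
            self.counts = c.round().astype(np.int64)
        zero = self.library_sizes() == 0
        if zero.any():
            raise DataValidationError(
                f"zero library size for sample(s): {list(self.counts.columns[zero])}"
            )

    # -- accessors -----------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        return read_count_matrix(path)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene ids, header sample ids)."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise DataValidationError(
                f"{path}: non-numeric count {bad.iloc[0]!r} for gene "
                f"{bad.index[0]!r} in sample {col!r}"
            )
    return CountMatrix(df)


@dataclass
class SampleMetadata:
    """Per-sample design annotations: species, colony, treatment, timepoint.

    Treatments are canonicalized case-insensitively to ``control``/``heated``;
    timepoints are integer hours.
    """

    table: pd.DataFrame
    timepoints: tuple[int, ...] = (4, 24)

    def __post_init__(self) -> None:
        t = self.table
        required = {"species", "colony", "treatment", "timepoint_h"}
        missing = required - set(t.columns)
        if missing:
            raise DataValidationError(f"metadata missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dup[:5]}")
        canon = t["treatment"].astype(str).str.strip().str.lower()
        unknown = sorted(set(canon) - set(TREATMENTS))
        if unknown:
            raise DataValidationError(f"unknown treatment level(s): {unknown}")
        t = t.assign(treatment=canon, timepoint_h=t["timepoint_h"].astype(int))
        bad_tp = sorted(set(t["timepoint_h"]) - set(self.timepoints))
        if bad_tp:
            raise DataValidationError(
                f"timepoint(s) {bad_tp} outside declared set {self.timepoints}"
            )
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_where(
        self,
        treatment: str | None = None,
        timepoint_h: int | None = None,
        species: str | None = None,
    ) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if treatment is not None:
            mask &= self.table["treatment"] == treatment
        if timepoint_h is not None:
            mask &= self.table["timepoint_h"] == int(timepoint_h)
        if species is not None:
            mask &= self.table["species"] == species
        return list(self.table.index[mask])

    def group_labels(self) -> pd.Series:
        """treatment x timepoint cell label per sample, e.g. ``heated_24h``."""
        t = self.table
        return t["treatment"] + "_" + t["timepoint_h"].astype(str) + "h"

    @classmethod
    def from_tsv(cls, path: str | Path, timepoints: tuple[int, ...] = (4, 24)):
        return read_metadata(path, timepoints=timepoints)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def read_metadata(
    path: str | Path, timepoints: tuple[int, ...] = (4, 24)
) -> SampleMetadata:
    """Read sample metadata TSV (sample_id, species, colony, treatment, timepoint_h)."""
    df = _read_tsv(path, dtype={0: str})
    if "sample_id" not in df.columns:
        raise DataValidationError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataValidationError(f"{path}: duplicate sample_id {dup[:5]}")
    df = df.set_index("sample_id")
    return SampleMetadata(df, timepoints=timepoints)


def validate_design(meta: SampleMetadata, counts: CountMatrix) -> dict:
    """Cross-check sample sets and summarize replicates per design cell.

    Returns a dict with per (species, treatment, timepoint) replicate counts
    and a ``warnings`` list flagging empty cells.  Raises when the two sample
    sets disagree, listing the orphans.
    """
    meta_ids = set(meta.sample_ids)
    count_ids = set(counts.sample_ids)
    only_counts = sorted(count_ids - meta_ids)
    only_meta = sorted(meta_ids - count_ids)
    if only_counts or only_meta:
        raise DataValidationError(
            f"sample sets disagree; in counts only: {only_counts}; "
            f"in metadata only: {only_meta}"
        )
    cells: dict[tuple, int] = {}
    warnings: list[str] = []
    t = meta.table
    for species in sorted(t["species"].unique()):
        for trt in TREATMENTS:
            for tp in meta.timepoints:
                n = int(
                    (
                        (t["species"] == species)
                        & (t["treatment"] == trt)
                        & (t["timepoint_h"] == tp)
                    ).sum()
                )
                cells[(species, trt, tp)] = n
                if n == 0:
                    warnings.append(f"empty design cell: {species}/{trt}/{tp}h")
    return {"cells": cells, "n_samples": len(meta_ids), "warnings": warnings}


# ---------------------------------------------------------------------------
# Hit tables, domain annotations, SRG family definitions, orthogroup counts
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read BLAST tabular hits (outfmt 6, optional 13th ``taxon`` column)."""
    df = _read_tsv(path, header=None, dtype={0: str, 1: str})
    if df.shape[1] == 12:
        df.columns = BLAST6_COLUMNS
    elif df.shape[1] == 13:
        df.columns = BLAST6_COLUMNS + ["taxon"]
    else:
        raise DataValidationError(
            f"{path}: expected 12 or 13 tab-separated columns, got {df.shape[1]}"
        )
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise DataValidationError(f"{path}: pident outside [0, 100]")
    if (df["evalue"] < 0).any():
        raise DataValidationError(f"{path}: negative e-value")
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_domain_table(path: str | Path) -> pd.DataFrame:
    """Read a simplified HMMER/Pfam domain table (gene_id, accession, evalue)."""
    df = _read_tsv(path, dtype={"gene_id": str, "accession": str})
    required = {"gene_id", "accession", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    if (df["evalue"] < 0).any():
        raise DataValidationError(f"{path}: negative domain e-value")
    return df


SRG_CATEGORIES = ("chemical", "pathogen", "wounding")


def read_srg_families(path: str | Path) -> pd.DataFrame:
    """Read SRG family definitions (family, category, comma-separated accessions).

    File order defines the family priority used to break multi-family gene
    assignments.
    """
    df = _read_tsv(path, dtype=str)
    required = {"family", "category", "accessions"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: missing columns {sorted(missing)}")
    if df["family"].duplicated().any():
        dup = df.loc[df["family"].duplicated(), "family"].tolist()
        raise DataValidationError(f"{path}: duplicate family name(s) {dup}")
    bad = sorted(set(df["category"]) - set(SRG_CATEGORIES))
    if bad:
        raise DataValidationError(f"{path}: unknown SRG category {bad}")
    df = df.assign(
        accessions=df["accessions"].map(
            lambda s: tuple(a.strip() for a in s.split(",") if a.strip())
        )
    )
    if (df["accessions"].map(len) == 0).any():
        raise DataValidationError(f"{path}: family with empty defining-domain set")
    return df


def default_srg_families() -> pd.DataFrame:
    """The example SRG family table shipped with the package.

    A small synthetic stand-in spanning the chemical / pathogen / wounding
    stress categories with real Pfam accessions; real analyses should supply
    their own curated table.
    """
    from importlib.resources import files

    path = files("coralstress").joinpath("data/srg_families.tsv")
    return read_srg_families(str(path))


def read_orthogroup_counts(path: str | Path) -> pd.DataFrame:
    """Read an Orthogroups.GeneCount-style table (orthogroup x species)."""
    df = _read_tsv(path, index_col=0)
    if df.index.has_duplicates:
        raise DataValidationError(f"{path}: duplicate orthogroup ids")
    if df.columns.has_duplicates:
        raise DataValidationError(f"{path}: duplicate species columns")
    df = df.drop(columns=[c for c in df.columns if c.lower() == "total"])
    if (df.to_numpy() < 0).any():
        raise DataValidationError(f"{path}: negative orthogroup gene count")
    return df.astype(int)
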