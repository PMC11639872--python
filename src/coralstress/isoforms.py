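"""Isoform selection and coding-sequence retention for de novo assemblies.

RSEM reports, per library, the percentage of a transcript's expression
attributed to each isoform (IsoPct).  The retention rules applied here:

1. drop isoforms whose combined IsoPct (summed across libraries) is zero;
2. keep one representative isoform per transcript — highest combined IsoPct,
   ties broken by longest length, then lexicographic isoform id;
3. keep only protein-coding isoforms (the coding flag is an input; ORF
   prediction happens upstream).

The pipeline of the three filters is idempotent and never invents ids.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("transcript_id", "isoform_id", "iso_pct", "length", "is_coding")

__all__ = [
    "drop_zero_isopct",
    "select_representative_isoform",
    "coding_filter",
    "filter_isoforms",
    "read_isoform_table",
    "combine_isopct",
]


def _check(records: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"isoform table missing columns: {sorted(missing)}")
    if ((records["iso_pct"] < 0) | (records["iso_pct"] > 100 * 1e6)).any():
        raise ValueError("combined iso_pct must be non-negative")
    if (records["length"] < 1).any():
        raise ValueError("isoform lengths must be >= 1 nt")


def read_isoform_table(path) -> pd.DataFrame:
    """Read an isoform table TSV (RSEM isoforms.results-like, pre-aggregated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str, "isoform_id": str})
    _check(df)
    return df


def combine_isopct(per_library: pd.DataFrame) -> pd.DataFrame:
    """Sum per-library IsoPct values into one combined value per isoform.

    Input columns: transcript_id, isoform_id, length, is_coding, iso_pct
    (one row per isoform per library).
    """
    keys = ["transcript_id", "isoform_id", "length", "is_coding"]
    out = per_library.groupby(keys, as_index=False)["iso_pct"].sum()
    return out


def drop_zero_isopct(records: pd.DataFrame) -> pd.DataFrame:
    """Remove isoforms with zero combined IsoPct; log vanished transcripts."""
    if records.empty:
        return records
    _check(records)
    kept = records[records["iso_pct"] > 0]
    gone = set(records["transcript_id"]) - set(kept["transcript_id"])
    if gone:
        logger.info(
            "%d transcript(s) removed entirely (all isoforms at zero IsoPct): %s",
            len(gone),
            sorted(gone)[:5],
        )
    return kept


def select_representative_isoform(records: pd.DataFrame) -> pd.DataFrame:
    """One isoform per transcript: argmax combined IsoPct, then longest, then id."""
    if records.empty:
        return records
    _check(records)
    ordered = records.sort_values(
        ["transcript_id", "iso_pct", "length", "isoform_id"],
        ascending=[True, False, False, True],
        kind="stable",
    )
    return ordered.groupby("transcript_id", sort=False).head(1)


def coding_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep protein-coding isoforms only."""
    if records.empty:
        return records
    _check(records)
    kept = records[records["is_coding"].astype(bool)]
    if kept.empty:
        logger.warning("no coding isoforms survive the coding filter")
    return kept


def filter_isoforms(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the three retention rules in order (idempotent)."""
    return coding_filter(select_representative_isoform(drop_zero_isopct(records)))
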