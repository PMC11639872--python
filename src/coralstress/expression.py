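"""Normalization and transforms: CPM, TPM, expression filtering, TMM,
median-ratio size factors, a variance-stabilizing log transform, and
fold changes with a prior count.

The transform used for ordination and plasticity is
``log2(count / size_factor + 1)`` on DESeq-style median-of-ratios size
factors — a depth-corrected, variance-stabilizing log scale standing in for
shrinkage-based regularized-log transforms (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import CountMatrix

__all__ = [
    "cpm",
    "tpm",
    "expression_filter",
    "tmm_factors",
    "size_factors_median_ratio",
    "vst_transform",
    "log2fc_with_prior",
]


def _counts_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def cpm(counts: CountMatrix | pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: ``count / library_size * 1e6`` per sample.

    ``lib_sizes`` overrides the column sums (e.g. TMM-effective sizes).
    """
    c = _counts_frame(counts)
    if lib_sizes is None:
        lib_sizes = c.sum(axis=0)
    lib_sizes = lib_sizes.reindex(c.columns)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"zero/negative library size for sample(s): {bad}")
    return c / lib_sizes * 1e6


def tpm(counts: CountMatrix | pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million given per-gene lengths (nt).

    Per sample: rate = count / length; value = rate / sum(rate) * 1e6.
    """
    c = _counts_frame(counts)
    lengths = pd.Series(lengths).reindex(c.index)
    if lengths.isna().any():
        missing = list(c.index[lengths.isna()])[:5]
        raise ValueError(f"missing length for gene(s): {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = c.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom <= 0).any():
        raise ValueError("sample with zero total rate; cannot compute TPM")
    return rate / denom * 1e6


def expression_filter(
    cpm_matrix: pd.DataFrame, min_cpm: float = 2.0, min_libraries: int = 2
) -> pd.Index:
    """Genes with > ``min_cpm`` CPM (strict) in at least ``min_libraries`` libraries."""
    n_pass = (cpm_matrix > min_cpm).sum(axis=1)
    return cpm_matrix.index[n_pass >= min_libraries]


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (composition correction).

    M-values (log2 relative expression vs the reference sample) are doubly
    trimmed — ``trim_m`` on each M tail, ``trim_a`` on each A (abundance)
    tail — and averaged with inverse-asymptotic-variance weights.  Factors are
    rescaled to geometric mean 1; the effective library size of a sample is
    ``library_size * factor``.  The reference defaults to the sample whose
    75th-percentile relative abundance is closest to the mean across samples.
    """
    c = _counts_frame(counts)
    if c.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = c.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    rel = c.div(lib, axis=1)
    if ref_sample is None:
        q75 = rel.quantile(0.75, axis=0)
        ref_sample = (q75 - q75.mean()).abs().idxmin()
    yr = c[ref_sample].to_numpy(dtype=float)
    nr = lib[ref_sample]
    factors = {}
    for s in c.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        yk = c[s].to_numpy(dtype=float)
        nk = lib[s]
        keep = (yk > 0) & (yr > 0)
        if not keep.any():
            factors[s] = 1.0
            continue
        fk, fr = yk[keep] / nk, yr[keep] / nr
        m = np.log2(fk / fr)
        a = 0.5 * np.log2(fk * fr)
        # asymptotic variance of M by the delta method; weight = 1 / var
        v = (nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m))
        lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a))
        rank_m = np.argsort(np.argsort(m, kind="stable"), kind="stable")
        rank_a = np.argsort(np.argsort(a, kind="stable"), kind="stable")
        sel = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if not sel.any():
            sel = np.ones(n, dtype=bool)
        with np.errstate(divide="ignore"):
            w = 1.0 / v[sel]
        f = np.sum(w * m[sel]) / np.sum(w)
        factors[s] = float(2.0**f)
    out = pd.Series(factors).reindex(c.columns)
    return out / np.exp(np.log(out).mean())


def size_factors_median_ratio(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean pseudo-reference.

    Only genes with positive counts in every sample enter the reference.
    """
    c = _counts_frame(counts).astype(float)
    positive = (c > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; median-ratio size "
            "factors are undefined (filter low-expression genes or supply a "
            "deeper matrix)"
        )
    sub = c.loc[positive]
    log_ref = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))


def vst_transform(
    counts: CountMatrix | pd.DataFrame, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Depth-corrected log transform: ``log2(count / size_factor + 1)``.

    Monotone per sample and deterministic; used as input to PCA, PERMANOVA,
    and the plasticity distance.
    """
    c = _counts_frame(counts)
    if size_factors is None:
        size_factors = size_factors_median_ratio(c)
    norm = c.div(size_factors.reindex(c.columns), axis=1)
    return np.log2(norm + 1.0)


def log2fc_with_prior(mean_a, mean_b, prior: float = 0.5):
    """``log2((mean_b + prior) / (mean_a + prior))`` — B relative to A.

    The symmetric prior count keeps zero-containing means finite; swapping
    the groups flips the sign exactly.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("group means must be non-negative")
    out = np.log2((b + prior) / (a + prior))
    if np.isscalar(mean_a) and np.isscalar(mean_b):
        return float(out)
    if isinstance(mean_a, pd.Series) or isinstance(mean_b, pd.Series):
        idx = mean_a.index if isinstance(mean_a, pd.Series) else mean_b.index
        return pd.Series(out, index=idx)
    return out
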