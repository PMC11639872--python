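"""Negative-binomial exact-test differential expression.

Two-group, time-matched comparisons (control vs heated at 4 h or 24 h) are
tested per gene with a conditional exact test: given the gene's total count
across both groups on depth-equalized libraries, the group split is compared
against its conditional distribution under equal means.  With NB(mu, phi)
counts (variance mu + phi mu^2) and n_g replicates per group, the group sum
is NB with size n_g / phi and the shared success probability, so the
conditional pmf of the group-A total is a ratio of NB pmfs; at phi = 0 it
reduces to the binomial conditional (Poisson limit).  Two-sided p-values
double the smaller tail (capped at 1) — deterministic and conservative for
skewed conditionals.

Dispersion is a single common phi maximizing the NB conditional
log-likelihood given per-group totals (qCML style) on pseudo-counts rescaled
to a common effective depth.

Genes pass to testing after the CPM filter (> 2 CPM in at least two
libraries); calls use the |log2FC| >= 4 and FDR < 0.05 thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core_data import CountMatrix, SampleMetadata
from .expression import cpm, expression_filter, log2fc_with_prior, tmm_factors

__all__ = [
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "classify_de",
    "de_analysis",
    "summarize_deg_counts",
    "relative_expression_ratio",
    "equalize_counts",
]

LFC_MIN_DEFAULT = 4.0
FDR_MAX_DEFAULT = 0.05


def equalize_counts(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Rescale counts to the geometric-mean effective depth and round.

    A pragmatic stand-in for quantile-to-quantile NB pseudo-count adjustment:
    each library is scaled to the common depth and rounded half-to-even so
    the exact test sees integer counts on comparable libraries.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    lib_sizes = lib_sizes.reindex(counts.columns).astype(float)
    common = float(np.exp(np.log(lib_sizes).mean()))
    scaled = counts * (common / lib_sizes)
    return scaled.round().astype(np.int64)


def _conditional_logpmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log P(Y_A = a | Y_A + Y_B = total) for a = 0..total under equal means."""
    a = np.arange(total + 1)
    b = total - a
    if phi > 0:
        r_a, r_b = n_a / phi, n_b / phi
        ll = (
            gammaln(a + r_a)
            - gammaln(a + 1)
            - gammaln(r_a)
            + gammaln(b + r_b)
            - gammaln(b + 1)
            - gammaln(r_b)
        )
    else:  # Poisson limit: binomial split with weight n_a/(n_a+n_b)
        q = n_a / (n_a + n_b)
        ll = (
            gammaln(total + 1)
            - gammaln(a + 1)
            - gammaln(b + 1)
            + a * np.log(q)
            + b * np.log1p(-q)
        )
    return ll - logsumexp(ll)


def nb_exact_test(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    phi: float,
    lib_sizes: pd.Series | None = None,
    equalize: bool = True,
) -> pd.Series | np.ndarray:
    """Two-sided conditional exact p-value per gene (rows = genes).

    ``counts_a`` / ``counts_b`` hold replicate columns for the two groups.
    Libraries are depth-equalized first unless ``equalize=False`` (pass
    pre-equalized integer counts then).  Genes with zero total have p = 1.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a_df = isinstance(counts_a, pd.DataFrame)
    A = np.asarray(counts_a)
    B = np.asarray(counts_b)
    if not (np.issubdtype(A.dtype, np.integer) and np.issubdtype(B.dtype, np.integer)):
        if not (np.allclose(A, np.rint(A)) and np.allclose(B, np.rint(B))):
            raise ValueError("exact test requires integer counts")
        A, B = np.rint(A).astype(np.int64), np.rint(B).astype(np.int64)
    if equalize:
        joint = np.hstack([A, B]).astype(np.int64)
        cols = pd.RangeIndex(joint.shape[1])
        joint_df = pd.DataFrame(joint, columns=cols)
        ls = None
        if lib_sizes is not None:
            ls = pd.Series(np.asarray(lib_sizes, dtype=float), index=cols)
        eq = equalize_counts(joint_df, ls).to_numpy()
        A, B = eq[:, : A.shape[1]], eq[:, A.shape[1]:]
    n_a, n_b = A.shape[1], B.shape[1]
    sa = A.sum(axis=1)
    totals = sa + B.sum(axis=1)
    pvals = np.ones(A.shape[0])
    # cache pmfs by total: many genes share small totals
    cache: dict[int, np.ndarray] = {}
    for i, (t, obs) in enumerate(zip(totals, sa)):
        t = int(t)
        if t == 0:
            continue
        logpmf = cache.get(t)
        if logpmf is None:
            logpmf = _conditional_logpmf(t, n_a, n_b, phi)
            if t <= 512:
                cache[t] = logpmf
        pmf = np.exp(logpmf)
        lower = pmf[: obs + 1].sum()
        upper = pmf[obs:].sum()
        pvals[i] = min(1.0, 2.0 * min(lower, upper))
    if a_df:
        return pd.Series(pvals, index=counts_a.index, name="pvalue")
    return pvals


def estimate_common_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: pd.Series | np.ndarray,
    equalize: bool = True,
    phi_max: float = 5.0,
) -> float:
    """Common NB dispersion maximizing the conditional log-likelihood.

    The likelihood of the within-group counts conditional on each group total
    is free of the gene means, leaving phi as the only parameter; the sum
    over genes and groups is maximized on a bounded log-scale search and
    floored at 0.  Requires replication in at least one group.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    groups = pd.Series(np.asarray(groups), index=c.columns)
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError(
            "no group has replicates; common dispersion is not estimable "
            "(pass a fixed phi to the exact test instead)"
        )
    mat = equalize_counts(c) if equalize else c.astype(np.int64)
    blocks = [
        mat.loc[:, groups.index[groups == g]].to_numpy()
        for g in sizes.index
        if sizes[g] >= 2
    ]

    def cond_ll(phi: float) -> float:
        ll = 0.0
        for y in blocks:
            n = y.shape[1]
            z = y.sum(axis=1)
            keep = z > 0
            if not keep.any():
                continue
            yk, zk = y[keep], z[keep]
            if phi > 0:
                r = 1.0 / phi
                ll += float(
                    np.sum(gammaln(yk + r) - gammaln(yk + 1))
                    - yk.shape[0] * n * gammaln(r)
                    + np.sum(gammaln(n * r) - gammaln(zk + n * r) + gammaln(zk + 1))
                )
            else:  # Poisson limit: multinomial conditional
                ll += float(
                    np.sum(gammaln(zk + 1)) - np.sum(gammaln(yk + 1))
                    - np.sum(zk * np.log(n))
                )
        return ll

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda lp: -cond_ll(10.0**lp),
        bounds=(-8.0, np.log10(phi_max)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = float(10.0 ** res.x)
    if cond_ll(0.0) >= -res.fun - 1e-9 or phi_hat < 1e-6:
        return 0.0
    return phi_hat


def bh_adjust(pvalues) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        out = p
    else:
        out = multipletests(p, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="fdr")
    return out


def classify_de(
    log2fc, fdr, lfc_min: float = LFC_MIN_DEFAULT, fdr_max: float = FDR_MAX_DEFAULT
):
    """Call up / down / ns at |log2FC| >= ``lfc_min`` and FDR < ``fdr_max``."""
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(fdr, dtype=float)
    status = np.where(
        (lfc >= lfc_min) & (q < fdr_max),
        "up",
        np.where((lfc <= -lfc_min) & (q < fdr_max), "down", "ns"),
    )
    if np.isscalar(log2fc):
        return str(status.item() if status.ndim == 0 else status[0])
    if isinstance(log2fc, pd.Series):
        return pd.Series(status, index=log2fc.index, name="status")
    return status


@dataclass
class DEOptions:
    min_cpm: float = 2.0
    min_libraries: int = 2
    lfc_min: float = LFC_MIN_DEFAULT
    fdr_max: float = FDR_MAX_DEFAULT
    prior_count: float = 0.5
    phi: float | None = None  # fixed dispersion override


def de_analysis(
    counts: CountMatrix,
    meta: SampleMetadata,
    timepoint_h: int,
    options: DEOptions | None = None,
) -> pd.DataFrame:
    """Control-vs-heated exact-test DE at one timepoint.

    Returns a per-gene frame (filtered genes only) with ``log2fc`` (heated
    relative to control, prior-count fold change on TMM-effective CPM means),
    ``pvalue``, ``fdr`` and ``status``.
    """
    opt = options or DEOptions()
    ctrl = meta.samples_where(treatment="control", timepoint_h=timepoint_h)
    heat = meta.samples_where(treatment="heated", timepoint_h=timepoint_h)
    if not ctrl or not heat:
        raise ValueError(f"missing control or heated samples at {timepoint_h} h")
    sub = counts.counts[ctrl + heat]
    factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors
    cpm_eff = cpm(sub, lib_sizes=eff_lib)
    keep = expression_filter(cpm_eff, opt.min_cpm, opt.min_libraries)
    sub = sub.loc[keep]
    cpm_eff = cpm_eff.loc[keep]
    groups = pd.Series(
        ["control"] * len(ctrl) + ["heated"] * len(heat), index=ctrl + heat
    )
    eq = equalize_counts(sub, eff_lib)
    phi = opt.phi
    if phi is None:
        phi = estimate_common_dispersion(eq, groups, equalize=False)
    pvals = nb_exact_test(eq[ctrl], eq[heat], phi, equalize=False)
    fdr = bh_adjust(pvals)
    lfc = log2fc_with_prior(
        cpm_eff[ctrl].mean(axis=1), cpm_eff[heat].mean(axis=1), opt.prior_count
    )
    res = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "status": classify_de(lfc, fdr, opt.lfc_min, opt.fdr_max),
        }
    )
    res.index.name = "gene_id"
    res["timepoint_h"] = timepoint_h
    res["phi"] = phi
    return res


def summarize_deg_counts(
    results: pd.DataFrame, by: tuple[str, ...] = ("species", "timepoint_h", "origin")
) -> pd.DataFrame:
    """Up/down DEG counts per grouping (species x timepoint x origin bin)."""
    cols = [c for c in by if c in results.columns]
    if not cols:
        up = int((results["status"] == "up").sum())
        down = int((results["status"] == "down").sum())
        return pd.DataFrame({"n_up": [up], "n_down": [down]})
    out = (
        results.groupby(cols, observed=True)["status"]
        .agg(
            n_up=lambda s: int((s == "up").sum()),
            n_down=lambda s: int((s == "down").sum()),
        )
        .reset_index()
    )
    return out


def relative_expression_ratio(
    tpm_matrix: pd.DataFrame,
    meta: SampleMetadata,
    gene_set,
    timepoint_h: int,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Mean heated TPM over mean time-matched control TPM, per gene.

    A zero control mean triggers the symmetric prior on both means and a
    ``prior_used`` flag, keeping the ratio finite.
    """
    genes = list(gene_set)
    missing = [g for g in genes if g not in tpm_matrix.index]
    if missing:
        raise KeyError(f"gene(s) absent from TPM matrix: {missing[:5]}")
    ctrl = meta.samples_where(treatment="control", timepoint_h=timepoint_h)
    heat = meta.samples_where(treatment="heated", timepoint_h=timepoint_h)
    if not ctrl or not heat:
        raise ValueError(f"missing control or heated samples at {timepoint_h} h")
    m_ctrl = tpm_matrix.loc[genes, ctrl].mean(axis=1)
    m_heat = tpm_matrix.loc[genes, heat].mean(axis=1)
    flagged = m_ctrl == 0
    ratio = pd.Series(np.nan, index=m_ctrl.index)
    ratio[~flagged] = m_heat[~flagged] / m_ctrl[~flagged]
    ratio[flagged] = (m_heat[flagged] + prior) / (m_ctrl[flagged] + prior)
    return pd.DataFrame(
        {
            "mean_tpm_control": m_ctrl,
            "mean_tpm_heated": m_heat,
            "ratio": ratio,
            "prior_used": flagged,
            "timepoint_h": timepoint_h,
        }
    )
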