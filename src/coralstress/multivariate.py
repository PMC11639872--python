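"""Ordination and multivariate treatment statistics.

PCA on the variance-stabilized matrix (top-variance genes), a permutational
MANOVA (pseudo-F on a distance matrix with a permutation p-value), the
transcriptome plasticity distance — Euclidean distance of each sample's
profile from the centroid of the 4 h control group — and one-way ANOVA with
Tukey HSD post-hoc contrasts on plasticity across treatment x timepoint
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core_data import SampleMetadata

__all__ = [
    "pca",
    "PCAResult",
    "euclidean_distance_matrix",
    "permanova",
    "PermanovaResult",
    "plasticity_distance",
    "anova_oneway",
    "tukey_hsd",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        vr = np.asarray(self.variance_ratio, dtype=float)
        assert np.all(np.diff(vr) <= 1e-12) and vr.sum() <= 1 + 1e-9
        self.variance_ratio = vr


def pca(
    matrix: pd.DataFrame,
    n_components: int | None = None,
    n_top_genes: int = 500,
    center: bool = True,
) -> PCAResult:
    """PCA of samples over the ``n_top_genes`` highest-variance genes.

    ``matrix`` is genes x samples on a log scale (vst).  Genes are centered;
    scores are returned per sample with the fraction of variance per
    component.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    var = matrix.var(axis=1)
    if float(var.max()) == 0.0:
        raise ValueError("constant matrix: PCA undefined")
    top = var.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    x = matrix.loc[top].T.to_numpy(dtype=float)  # samples x genes
    if n_components is None:
        n_components = min(x.shape[0] - 1, x.shape[1], 10)
    if center:
        model = PCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(x)
        ratio = model.explained_variance_ratio_
    else:  # uncentered SVD decomposition of the raw matrix
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        scores = (u * s)[:, :n_components]
        ratio = (s[:n_components] ** 2) / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        variance_ratio=ratio,
    )


def euclidean_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns of ``matrix``)."""
    x = matrix.T.to_numpy(dtype=float)
    d = np.sqrt(
        np.maximum(
            0.0,
            (x**2).sum(1)[:, None] + (x**2).sum(1)[None, :] - 2.0 * x @ x.T,
        )
    )
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    pvalue: float
    n_permutations: int
    warnings: tuple[str, ...] = ()


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    df_between, df_within = n_groups - 1, n - n_groups
    if ss_within <= 0 or df_within <= 0:
        return np.inf if ss_between > 0 else 0.0, (
            ss_between / ss_total if ss_total > 0 else 0.0
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist_matrix: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F with a free label-permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (n_perm + 1), so p is never 0.
    With ``exhaustive=True`` all distinct label orderings are enumerated
    (including the observed one) and p is the exact fraction with
    F >= observed.
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or (d < 0).any():
        raise ValueError("distance matrix must be symmetric and non-negative")
    labels = pd.Series(np.asarray(groups))
    if labels.size != d.shape[0]:
        raise ValueError("group labels do not match distance matrix size")
    uniq = labels.unique()
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    warnings = []
    if (labels.value_counts() < 2).any():
        warnings.append("group with a single member; within-group SS is partial")
    codes = pd.Categorical(labels, categories=uniq).codes.astype(np.int64)
    k = uniq.size
    d2 = d**2
    f_obs, r2 = _pseudo_f(d2, codes, k)
    if exhaustive:
        seen = set()
        count = total = 0
        for perm in permutations(codes.tolist()):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_p, _ = _pseudo_f(d2, np.asarray(perm), k)
            if f_p >= f_obs - 1e-12:
                count += 1
        return PermanovaResult(f_obs, r2, count / total, total, tuple(warnings))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = _pseudo_f(d2, rng.permutation(codes), k)
        if f_p >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        f_obs, r2, (1 + hits) / (n_perm + 1), n_perm, tuple(warnings)
    )


def plasticity_distance(
    matrix: pd.DataFrame,
    meta: SampleMetadata,
    reference: tuple[str, int] = ("control", 4),
    space: str = "full",
    n_components: int = 2,
    n_top_genes: int = 500,
) -> pd.DataFrame:
    """Per-sample transcriptome plasticity.

    Euclidean distance of each sample's profile from the mean profile
    (centroid) of the reference group — by default the 4 h controls — in the
    full transformed gene space (``space="full"``) or in the first
    ``n_components`` PC scores (``space="pca"``).
    """
    ref_samples = meta.samples_where(treatment=reference[0], timepoint_h=reference[1])
    ref_samples = [s for s in ref_samples if s in matrix.columns]
    if not ref_samples:
        raise ValueError(f"empty reference group {reference}")
    if space == "full":
        coords = matrix.T  # samples x genes
    elif space == "pca":
        res = pca(matrix, n_components=n_components, n_top_genes=n_top_genes)
        coords = res.scores
    else:
        raise ValueError("space must be 'full' or 'pca'")
    centroid = coords.loc[ref_samples].mean(axis=0)
    dist = np.sqrt(((coords - centroid) ** 2).sum(axis=1))
    out = pd.DataFrame(
        {"distance": dist, "group": meta.group_labels().reindex(coords.index)}
    )
    out.index.name = "sample_id"
    return out


def anova_oneway(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over group labels.

    Degenerate all-equal data (zero variance everywhere, equal means) returns
    (0.0, 1.0) by convention.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    samples = [v[g == lvl].to_numpy() for lvl in g.unique()]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if all(s.var(ddof=1) == 0 for s in samples if s.size > 1):
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            return 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts (studentized-range family-wise control).

    Returns one row per unordered pair with the mean difference, adjusted
    p-value, and a significance flag at ``alpha``.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    levels = list(g.unique())
    if len(levels) < 2:
        return pd.DataFrame(
            columns=["group_a", "group_b", "mean_diff", "p_adj", "significant"]
        )
    samples = [v[g == lvl].to_numpy() for lvl in levels]
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": float(samples[j].mean() - samples[i].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "significant": bool(res.pvalue[i, j] < alpha),
                }
            )
    return pd.DataFrame(rows)
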