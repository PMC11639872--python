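"""PCA sanity, PERMANOVA vs enumeration/skbio, plasticity, ANOVA/Tukey."""

import numpy as np
import pandas as pd
import pytest

from coralstress.core_data import SampleMetadata
from coralstress.multivariate import (
    anova_oneway,
    euclidean_distance_matrix,
    pca,
    permanova,
    plasticity_distance,
    tukey_hsd,
)


def two_cluster_matrix():
    rng = np.random.default_rng(0)
    left = rng.normal(0, 0.01, (20, 3))
    right = rng.normal(5, 0.01, (20, 3))
    mat = np.hstack([left, right])
    return pd.DataFrame(
        mat, index=[f"g{i}" for i in range(20)], columns=[f"s{j}" for j in range(6)]
    )


class TestPCA:
    def test_two_clusters_dominate_pc1(self):
        res = pca(two_cluster_matrix(), n_top_genes=20)
        assert res.variance_ratio[0] > 0.99
        pc1 = res.scores["PC1"]
        assert np.sign(pc1[:3]).nunique() == 1 and np.sign(pc1[3:]).nunique() == 1
        assert np.sign(pc1.iloc[0]) != np.sign(pc1.iloc[5])

    def test_duplicate_samples_get_identical_scores(self):
        mat = two_cluster_matrix()
        mat["s6"] = mat["s0"]
        res = pca(mat, n_top_genes=20)
        assert np.allclose(res.scores.loc["s0"], res.scores.loc["s6"], atol=1e-9)

    def test_variance_fractions_non_increasing_and_bounded(self, small_sim):
        from coralstress.expression import vst_transform

        cm = small_sim[0]
        res = pca(vst_transform(cm.counts))
        assert (np.diff(res.variance_ratio) <= 1e-12).all()
        assert res.variance_ratio.sum() <= 1 + 1e-9

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValueError, match="constant"):
            pca(mat)


def enumeration_permanova_p(coords, labels):
    """Exhaustive PERMANOVA oracle: direct SS computation per labelling."""
    from itertools import permutations

    coords = np.asarray(coords, dtype=float)
    n = len(labels)

    def f_stat(lab):
        groups = {}
        for i, g in enumerate(lab):
            groups.setdefault(g, []).append(i)
        grand = coords.mean(axis=0)
        ss_t = ((coords - grand) ** 2).sum()
        ss_w = 0.0
        for idx in groups.values():
            cen = coords[idx].mean(axis=0)
            ss_w += ((coords[idx] - cen) ** 2).sum()
        a = len(groups)
        return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))

    f_obs = f_stat(labels)
    seen = set()
    count = total = 0
    for perm in permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if f_stat(perm) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total


class TestPermanova:
    def test_two_far_pairs_exhaustive_third(self):
        coords = np.array([[0.0], [0.1], [10.0], [10.1]])
        mat = pd.DataFrame(coords.T, columns=list("abcd"))
        d = euclidean_distance_matrix(mat)
        res = permanova(d, ["g1", "g1", "g2", "g2"], exhaustive=True)
        assert res.pvalue == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 7
        coords = rng.normal(0, 1, (n, 3))
        labels = ["g1"] * 3 + ["g2"] * 2 + ["g3"] * 2
        mat = pd.DataFrame(coords.T, columns=[f"s{i}" for i in range(n)])
        d = euclidean_distance_matrix(mat)
        res = permanova(d, labels, exhaustive=True)
        f_expect, p_expect = enumeration_permanova_p(coords, tuple(labels))
        assert res.pseudo_f == pytest.approx(f_expect, rel=1e-9)
        assert res.pvalue == pytest.approx(p_expect, abs=1e-12)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        coords = rng.normal(0, 1, (9, 4))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        ids = [f"s{i}" for i in range(9)]
        mat = pd.DataFrame(coords.T, columns=ids)
        d = euclidean_distance_matrix(mat)
        res = permanova(d, labels, n_perm=99, seed=1)
        dm = skbio_stats.DistanceMatrix(d.to_numpy(), ids=ids)
        ref = skbio_stats.permanova(dm, grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(0, 1, (8, 3))
        labels = np.array(["g1"] * 4 + ["g2"] * 4)
        mat = pd.DataFrame(coords.T, columns=[f"s{i}" for i in range(8)])
        d = euclidean_distance_matrix(mat)
        f1 = permanova(d, labels, n_perm=9, seed=0).pseudo_f
        order = rng.permutation(8)
        d2 = d.iloc[order, order]
        f2 = permanova(d2, labels[order], n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(60):
            coords = rng.normal(0, 1, (8, 2))
            mat = pd.DataFrame(coords.T, columns=[f"s{i}" for i in range(8)])
            d = euclidean_distance_matrix(mat)
            labels = rng.permutation(["g1"] * 4 + ["g2"] * 4)
            pvals.append(permanova(d, labels, n_perm=199, seed=int(rng.integers(2**31))).pvalue)
        assert 0.2 < np.mean(pvals) < 0.8
        assert (np.array(pvals) >= 1 / 200).all()  # p never 0 by convention

    def test_single_group_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["g1", "g1", "g1"])


class TestPlasticity:
    def _meta(self):
        rows = []
        for colony in (1, 2, 3):
            for trt in ("control", "heated"):
                for tp in (4, 24):
                    rows.append(
                        {
                            "sample_id": f"c{colony}_{trt}_{tp}",
                            "species": "toy",
                            "colony": str(colony),
                            "treatment": trt,
                            "timepoint_h": tp,
                        }
                    )
        return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))

    def test_sample_at_centroid_has_zero_distance(self):
        meta = self._meta()
        mat = pd.DataFrame(
            np.zeros((2, 12)), index=["g0", "g1"], columns=meta.sample_ids
        )
        out = plasticity_distance(mat, meta)
        ref = meta.samples_where(treatment="control", timepoint_h=4)
        assert (out.loc[ref, "distance"] == 0).all()

    def test_pythagorean_distance(self):
        meta = self._meta()
        mat = pd.DataFrame(
            np.zeros((2, 12)), index=["g0", "g1"], columns=meta.sample_ids
        )
        mat.loc["g0", "c1_heated_24"] = 3.0
        mat.loc["g1", "c1_heated_24"] = 4.0
        out = plasticity_distance(mat, meta)
        assert out.loc["c1_heated_24", "distance"] == pytest.approx(5.0)

    def test_invariant_to_gene_order(self, small_sim):
        from coralstress.expression import vst_transform

        cm, meta, _, _ = small_sim
        vst = vst_transform(cm.counts)
        a = plasticity_distance(vst, meta)["distance"]
        b = plasticity_distance(vst.iloc[::-1], meta)["distance"]
        assert np.allclose(a, b)

    def test_empty_reference_errors(self):
        meta = self._meta()
        mat = pd.DataFrame(np.zeros((2, 12)), columns=meta.sample_ids)
        with pytest.raises(ValueError, match="reference"):
            plasticity_distance(mat, meta, reference=("control", 48))


class TestAnovaTukey:
    def test_two_group_f_equals_squared_t(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        values = np.concatenate([a, b])
        groups = ["a"] * 8 + ["b"] * 8
        f, p = anova_oneway(values, groups)
        t, p_t = ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(p_t, rel=1e-9)

    def test_identical_groups_give_f_zero(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        f, p = anova_oneway(values, ["a", "a", "a", "b", "b", "b"])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_equal_returns_p_one(self):
        f, p = anova_oneway([2.0] * 6, ["a", "a", "a", "b", "b", "b"])
        assert (f, p) == (0.0, 1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(40):
            a = rng.normal(0, 1, 5)
            b = rng.normal(5, 1, 5)  # 5 within-sd units
            _, p = anova_oneway(np.concatenate([a, b]), ["a"] * 5 + ["b"] * 5)
            hits += p < 0.01
        assert hits >= 38  # >= 95%

    def test_tukey_identical_groups_no_significance(self):
        values = [1.0, 2.0, 3.0] * 3
        out = tukey_hsd(values, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert not out["significant"].any()

    def test_tukey_shifted_group_flags_only_its_pairs(self):
        rng = np.random.default_rng(10)
        values = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(0, 1, 6), rng.normal(20, 1, 6)]
        )
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        out = tukey_hsd(values, groups).set_index(["group_a", "group_b"])
        assert bool(out.loc[("a", "c"), "significant"])
        assert bool(out.loc[("b", "c"), "significant"])
        assert not bool(out.loc[("a", "b"), "significant"])

    def test_tukey_symmetric_in_pair_order(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 12)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = tukey_hsd(values, groups)
        out_rev = tukey_hsd(values[::-1], list(reversed(groups)))
        a = out.assign(pair=[frozenset(x) for x in zip(out.group_a, out.group_b)])
        b = out_rev.assign(
            pair=[frozenset(x) for x in zip(out_rev.group_a, out_rev.group_b)]
        )
        merged = a.merge(b, on="pair", suffixes=("_f", "_r"))
        assert np.allclose(merged["p_adj_f"], merged["p_adj_r"], atol=1e-9)

    def test_single_group_gives_empty_table(self):
        assert tukey_hsd([1.0, 2.0], ["a", "a"]).empty
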