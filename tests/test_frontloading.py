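"""Frontloading rule, SRG distribution summaries, enrichment report."""

import numpy as np
import pandas as pd
import pytest

from coralstress.core_data import default_srg_families
from coralstress.diffexpr import de_analysis
from coralstress.expression import cpm
from coralstress.frontloading import (
    basal_expression,
    classify_frontloaded,
    frontloading_calls,
    frontloading_report,
    responsive_srg_summary,
    srg_expression_summary,
)
from coralstress.srg import assign_srg_families
from coralstress.synthetic import simulate_domains


class TestRule:
    def test_high_basal_stable_gene_is_frontloaded(self):
        assert classify_frontloaded(50.0, 10.0, 0.5, -0.3) is True

    def test_low_basal_never_frontloaded(self):
        assert classify_frontloaded(5.0, 10.0, 0.0, 0.0) is False

    def test_lfc_boundary_strict(self):
        assert classify_frontloaded(50.0, 10.0, 2.0, 0.1) is False
        assert classify_frontloaded(50.0, 10.0, 1.999, 0.1) is True

    def test_median_boundary_strict(self):
        assert classify_frontloaded(10.0, 10.0, 0.0, 0.0) is False

    def test_either_timepoint_rule_relaxes(self):
        assert (
            classify_frontloaded(50.0, 10.0, 3.0, 0.1, timepoint_rule="either") is True
        )


class TestBasal:
    def test_mean_over_control_libraries(self, toy_meta):
        mat = pd.DataFrame(
            0.0, index=["g0"], columns=toy_meta.sample_ids
        )
        ctrl = toy_meta.samples_where(treatment="control")
        mat.loc["g0", ctrl] = [10, 20, 30, 10, 20, 30]
        assert basal_expression(mat, toy_meta)["g0"] == pytest.approx(20.0)

    def test_no_controls_errors(self, toy_meta):
        heat = toy_meta.samples_where(treatment="heated")
        mat = pd.DataFrame(1.0, index=["g0"], columns=heat)
        with pytest.raises(ValueError, match="control"):
            basal_expression(mat, toy_meta)


@pytest.fixture(scope="module")
def planted_calls(default_sim):
    cm, meta, truth, cfg = default_sim
    de = pd.concat([de_analysis(cm, meta, tp) for tp in (4, 24)])
    calls = frontloading_calls(cpm(cm), meta, de)
    catalog = assign_srg_families(
        simulate_domains(truth, seed=21), default_srg_families()
    )
    return cm, meta, truth, de, calls, catalog


class TestPlantedRecovery:
    def test_precision_and_recall_against_planted_labels(self, planted_calls):
        _, _, truth, _, calls, catalog = planted_calls
        srg_calls = calls.loc[calls.index.intersection(catalog.index)]
        predicted = srg_calls["frontloaded"]
        actual = truth.loc[srg_calls.index, "planted_frontloaded"]
        tp = int((predicted & actual).sum())
        precision = tp / max(1, int(predicted.sum()))
        recall = tp / max(1, int(actual.sum()))
        assert precision >= 0.9 and recall >= 0.9

    def test_flags_mutually_exclusive(self, planted_calls):
        *_, calls, _ = planted_calls
        assert not (calls["frontloaded"] & calls["low_basal_responsive"]).any()

    def test_calls_invariant_to_gene_order(self, planted_calls):
        cm, meta, _, de, calls, _ = planted_calls
        reordered = frontloading_calls(cpm(cm).iloc[::-1], meta, de)
        assert (
            reordered["frontloaded"].sort_index() == calls["frontloaded"].sort_index()
        ).all()

    def test_responsive_srgs_recover_planted_fold_change(self, planted_calls):
        _, _, truth, de, calls, catalog = planted_calls
        summary = responsive_srg_summary(calls, de, catalog)
        up4 = summary["upregulated"].get(4, {})
        assert up4.get("n_up", 0) > 0
        assert 3.5 <= up4["mean_log2fc"] <= 4.5


class TestSummaries:
    def test_srg_median_above_all_gene_median(self, planted_calls):
        cm, meta, truth, de, _, catalog = planted_calls
        summary = srg_expression_summary(cpm(cm), catalog, meta, de)
        # frontloaded half of the SRG set is planted high-basal
        assert summary["n_srg_above_median"] > 0
        assert summary["n_srg"] == len(catalog.index.intersection(cm.gene_ids))
        assert (
            summary["n_srg_above_median"] + summary["n_srg_below_median"]
            == summary["n_srg"]
        )

    def test_srg_set_equal_to_all_genes_gives_equal_medians(self, toy_meta):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.lognormal(3, 1, (50, 12)),
            index=[f"g{i}" for i in range(50)],
            columns=toy_meta.sample_ids,
        )
        catalog = pd.DataFrame(
            {"family": ["F"] * 50, "category": ["chemical"] * 50}, index=mat.index
        )
        de = pd.DataFrame(
            {"log2fc": 0.0, "status": "ns", "timepoint_h": 4}, index=mat.index
        )
        summary = srg_expression_summary(mat, catalog, toy_meta, de)
        assert summary["median_srg"] == pytest.approx(summary["median_all"])

    def test_above_below_counts(self, toy_meta):
        mat = pd.DataFrame(
            np.arange(1, 11)[:, None] * np.ones((1, 12)),
            index=[f"g{i}" for i in range(10)],
            columns=toy_meta.sample_ids,
        )
        catalog = pd.DataFrame(
            {"family": ["F"] * 10, "category": ["chemical"] * 10}, index=mat.index
        )
        de = pd.DataFrame(
            {"log2fc": 0.0, "status": "ns", "timepoint_h": 4}, index=mat.index
        )
        s = srg_expression_summary(mat, catalog, toy_meta, de)
        assert s["n_srg_above_median"] == 5 and s["n_srg_below_median"] == 5

    def test_low_basal_mean_abs_lfc(self):
        calls = pd.DataFrame(
            {
                "basal_expr": [1.0, 2.0],
                "transcriptome_median": [10.0, 10.0],
                "log2fc_4h": [2.0, 4.0],
                "log2fc_24h": [1.0, 1.0],
                "frontloaded": [False, False],
                "low_basal_responsive": [False, False],
            },
            index=pd.Index(["g0", "g1"], name="gene_id"),
        )
        de = pd.DataFrame(
            {"log2fc": [2.0, 4.0], "status": ["ns", "ns"], "timepoint_h": [4, 4]},
            index=calls.index,
        )
        out = responsive_srg_summary(calls, de)
        assert out["mean_abs_log2fc"][4] == pytest.approx(3.0)

    def test_empty_low_basal_set_is_empty_not_error(self):
        calls = pd.DataFrame(
            {
                "basal_expr": [50.0],
                "transcriptome_median": [10.0],
                "log2fc_4h": [0.0],
                "log2fc_24h": [0.0],
                "frontloaded": [True],
                "low_basal_responsive": [False],
            },
            index=pd.Index(["g0"], name="gene_id"),
        )
        de = pd.DataFrame(
            {"log2fc": [0.0], "status": ["ns"], "timepoint_h": [4]}, index=calls.index
        )
        out = responsive_srg_summary(calls, de)
        assert out["n_low_basal"] == 0 and out["mean_abs_log2fc"] == {}


class TestEnrichmentReport:
    def _calls(self, front_flags):
        n = len(front_flags)
        return pd.DataFrame(
            {
                "basal_expr": 20.0,
                "transcriptome_median": 10.0,
                "log2fc_4h": 0.0,
                "log2fc_24h": 0.0,
                "frontloaded": front_flags,
                "low_basal_responsive": [False] * n,
            },
            index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"),
        )

    def test_fully_frontloaded_family_is_enriched(self):
        # family = genes 0-9 all frontloaded; background 10% frontloaded
        flags = [True] * 10 + [i % 10 == 0 for i in range(190)]
        calls = self._calls(flags)
        catalog = pd.DataFrame(
            {"family": ["target"] * 10 + ["other"] * 190, "category": "chemical"},
            index=calls.index,
        )
        out = frontloading_report(calls, catalog).set_index("family")
        assert bool(out.loc["target", "enriched"])

    def test_zero_frontloaded_family_not_flagged(self):
        flags = [False] * 10 + [True] * 20 + [False] * 70
        calls = self._calls(flags)
        catalog = pd.DataFrame(
            {"family": ["empty"] * 10 + ["other"] * 90, "category": "chemical"},
            index=calls.index,
        )
        out = frontloading_report(calls, catalog).set_index("family")
        assert not bool(out.loc["empty", "enriched"])
        assert out.loc["empty", "n_frontloaded"] == 0

    def test_family_equal_to_whole_transcriptome_p_one(self):
        flags = [True] * 30 + [False] * 70
        calls = self._calls(flags)
        catalog = pd.DataFrame(
            {"family": ["all"] * 100, "category": "chemical"}, index=calls.index
        )
        out = frontloading_report(calls, catalog).set_index("family")
        assert out.loc["all", "pvalue"] == pytest.approx(1.0)

    def test_hypergeometric_matches_direct_computation(self):
        from scipy.stats import hypergeom

        flags = [True] * 5 + [False] * 5 + [True] * 10 + [False] * 80
        calls = self._calls(flags)
        catalog = pd.DataFrame(
            {"family": ["f"] * 10 + ["rest"] * 90, "category": "chemical"},
            index=calls.index,
        )
        out = frontloading_report(calls, catalog).set_index("family")
        expect = hypergeom.sf(5 - 1, 100, 15, 10)
        assert out.loc["f", "pvalue"] == pytest.approx(expect, rel=1e-12)
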