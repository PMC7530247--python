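"""Cluster profiling tests: per-channel t-tests, clinical characterization,
three-group cohort comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmnstrat.montage import FRONTOCENTRAL_24
from mmnstrat.profiling import (characterize_clusters, cohort_group_comparison,
                                per_channel_cluster_ttests,
                                validate_cohort_table)
from mmnstrat.simulate import (clinical_table_cohort, profiles,
                               three_group_cohort_table)
from mmnstrat.stratify import FeatureMatrix


class FakeResult:
    """Duck-typed stand-in for a ClusterResult (assignments + labels)."""

    def __init__(self, assignments: pd.Series):
        self.assignments = assignments
        self.labels = {1: "Better functioning", 2: "Poorer functioning"}


def _matrix(values_by_cluster):
    rows, assign = [], {}
    i = 0
    for cluster, rows_c in values_by_cluster.items():
        for r in rows_c:
            rows.append(np.full(24, float(r)) if np.isscalar(r) else r)
            assign[f"s{i}"] = cluster
            i += 1
    data = pd.DataFrame(rows, index=list(assign), columns=list(FRONTOCENTRAL_24))
    return FeatureMatrix(data=data, source="mmn"), FakeResult(
        pd.Series(assign, name="cluster"))


class TestPerChannelTTests:
    def test_identical_distributions_null(self):
        fm, res = _matrix({1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0]})
        out = per_channel_cluster_ttests(fm, res)
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_hand_pooled_t(self):
        # {1,2,3} vs {4,5,6}: pooled SD 1, t = -3.674, p ~ 0.021, df 4
        fm, res = _matrix({1: [1.0, 2.0, 3.0], 2: [4.0, 5.0, 6.0]})
        out = per_channel_cluster_ttests(fm, res)
        assert out.loc[0, "pooled_sd"] == pytest.approx(1.0)
        assert out.loc[0, "t"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc[0, "p"] == pytest.approx(0.0214, abs=1e-3)
        assert out.loc[0, "df"] == 4
        assert out["significant"].all()

    def test_swapping_labels_negates_t(self):
        rng = np.random.default_rng(0)
        fm, res = _matrix({1: list(rng.normal(0, 1, 5)),
                           2: list(rng.normal(1, 1, 6))})
        out1 = per_channel_cluster_ttests(fm, res)
        swapped = FakeResult(res.assignments.map({1: 2, 2: 1}))
        out2 = per_channel_cluster_ttests(fm, swapped)
        np.testing.assert_allclose(out2["t"], -out1["t"], atol=1e-12)
        np.testing.assert_allclose(out2["p"], out1["p"], atol=1e-12)

    def test_singleton_cluster_untestable(self):
        fm, res = _matrix({1: [1.0], 2: [2.0, 3.0]})
        out = per_channel_cluster_ttests(fm, res)
        assert out["p"].isna().all()
        assert not out["significant"].any()
        assert out.loc[0, "mean_1"] == 1.0  # means still reported


def _assigned_table(table):
    obs = table["subject"].astype(str) + "@" + table["timepoint"]
    assign = pd.Series(table["true_cluster"].to_numpy(), index=obs.to_numpy())
    return FakeResult(assign)


class TestCharacterizeClusters:
    def test_planted_separation_detected(self):
        model = dict(profiles.CLINICAL_MODEL_MIXED)
        model["MCAS_social"] = {1: (20.0, 2.0), 2: (16.0, 2.0)}  # 2 SD apart
        table = clinical_table_cohort(27, 11, model,
                                      profiles.CATEGORICAL_MODEL_MIXED, seed=1)
        report = characterize_clusters(table, _assigned_table(table))
        row = report.variables.set_index("variable").loc["MCAS_social"]
        assert row["significant"]
        assert row["mean_1"] > row["mean_2"]

    def test_panss_na_for_mixed_hc_clusters(self):
        model = dict(profiles.CLINICAL_MODEL_MIXED)
        model["PANSS_total"] = {1: (50.0, 10.0), 2: (55.0, 10.0)}
        table = clinical_table_cohort(10, 10, model,
                                      profiles.CATEGORICAL_MODEL_MIXED,
                                      seed=2, groups=("HC", "HC"))
        report = characterize_clusters(table, _assigned_table(table))
        row = report.variables.set_index("variable").loc["PANSS_total"]
        assert np.isnan(row["p"]) and not row["significant"]

    def test_single_member_cluster_untestable(self):
        table = clinical_table_cohort(1, 10, seed=3)
        report = characterize_clusters(table, _assigned_table(table))
        cont = report.variables[report.variables.kind == "continuous"]
        assert cont["p"].isna().all()
        assert np.isnan(cont.iloc[0]["sd_1"])

    def test_report_is_pure_function_of_inputs(self):
        table = clinical_table_cohort(12, 14, seed=4)
        res = _assigned_table(table)
        r1 = characterize_clusters(table, res)
        r2 = characterize_clusters(table, res)
        pd.testing.assert_frame_equal(r1.variables, r2.variables)

    def test_unmatched_observation_listed(self):
        table = clinical_table_cohort(3, 3, seed=5)
        res = _assigned_table(table)
        res.assignments.index = [f"ghost{i}" for i in range(6)]
        with pytest.raises(ValueError, match="ghost0"):
            characterize_clusters(table, res)

    def test_markdown_render_bolds_significant(self):
        model = {"UPSA": {1: (90.0, 1.0), 2: (60.0, 1.0)}}
        table = clinical_table_cohort(8, 8, model, {}, seed=6)
        report = characterize_clusters(table, _assigned_table(table))
        md = report.to_markdown()
        assert "**UPSA**" in md


class TestCohortGroupComparison:
    def test_identical_groups_null_anova(self):
        rows = []
        for grp, tp in (("HC", "baseline"), ("FEP", "baseline"),
                        ("FEP", "followup")):
            for i, v in enumerate((1.0, 2.0, 3.0)):
                rows.append({"subject": f"{grp}{tp}{i}", "group": grp,
                             "timepoint": tp, "age": v})
        out = cohort_group_comparison(pd.DataFrame(rows))
        row = out.set_index("variable").loc["age"]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_hand_anova(self):
        # {1,2,3}, {1,2,3}, {4,5,6}: SSB = 18 (df 2), SSW = 6 (df 6),
        # so F = 9/1 = 9.0
        rows = []
        for (grp, tp), vals in ((("HC", "baseline"), (1, 2, 3)),
                                (("FEP", "baseline"), (1, 2, 3)),
                                (("FEP", "followup"), (4, 5, 6))):
            for i, v in enumerate(vals):
                rows.append({"subject": f"{grp}{tp}{i}", "group": grp,
                             "timepoint": tp, "age": float(v)})
        out = cohort_group_comparison(pd.DataFrame(rows))
        assert out.set_index("variable").loc["age", "statistic"] == \
            pytest.approx(9.0)

    def test_female_chi2_near_identical_proportions(self):
        # 12/33, 7/20, 6/18 females: chi2 ~ 0.05, p ~ 0.98
        rows = []
        for grp, tp, n, k, prefix in (("HC", "baseline", 33, 12, "C"),
                                      ("FEP", "baseline", 20, 7, "P"),
                                      ("FEP", "followup", 18, 6, "P")):
            for i in range(n):
                rows.append({"subject": f"{prefix}{i}", "group": grp,
                             "timepoint": tp, "female": i < k, "age": 20.0})
        out = cohort_group_comparison(pd.DataFrame(rows))
        row = out.set_index("variable").loc["female"]
        expected_chi2, expected_p, *_ = stats.chi2_contingency(
            [[12, 21], [7, 13], [6, 12]], correction=False)[:2], None
        assert row["statistic"] == pytest.approx(0.05, abs=0.03)
        assert row["p"] > 0.9

    def test_panss_compared_between_patient_groups_only(self):
        table = three_group_cohort_table(seed=7)
        out = cohort_group_comparison(table).set_index("variable")
        assert out.loc["PANSS_total", "test"] == "t"
        assert out.loc["age", "test"] == "F"
        assert np.isnan(out.loc["PANSS_total", "mean_HC"])

    def test_one_sided_halves_p(self):
        table = three_group_cohort_table(seed=8)
        two = cohort_group_comparison(table).set_index("variable")
        one = cohort_group_comparison(table, one_sided=True).set_index("variable")
        assert one.loc["PANSS_total", "p"] == \
            pytest.approx(two.loc["PANSS_total", "p"] / 2)

    def test_empty_group_rejected(self):
        table = three_group_cohort_table(seed=9)
        with pytest.raises(ValueError, match="empty"):
            cohort_group_comparison(table[table["group"] == "HC"])


class TestCohortTableValidation:
    def test_hc_with_panss_rejected(self):
        table = three_group_cohort_table(seed=10)
        bad = table.copy()
        bad.loc[bad["group"] == "HC", "PANSS_total"] = 50.0
        with pytest.raises(ValueError, match="PANSS_total"):
            validate_cohort_table(bad)

    def test_upsa_range_enforced(self):
        table = three_group_cohort_table(seed=11)
        bad = table.copy()
        bad.loc[bad.index[0], "UPSA"] = 140.0
        with pytest.raises(ValueError, match="UPSA"):
            validate_cohort_table(bad)

    def test_valid_table_passes(self):
        table = three_group_cohort_table(seed=12)
        assert validate_cohort_table(table) is table
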