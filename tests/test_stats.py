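"""Statistics layer: t-tests, OLS, calibration, summary tables."""

import numpy as np
import pandas as pd
import pytest

from atriastasis.stats import (
    group_summary,
    shape_subgroup_analysis,
    two_sample_ttest,
    univariate_regression,
    validate_cohort_table,
)


class TestTTest:
    def test_hand_computed_pooled_t(self):
        """a = 1..5, b = 2..6: mean diff -1, pooled SD sqrt(2.5), SE 1."""
        res = two_sample_ttest([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.t == pytest.approx(-1.0)
        assert res.p == pytest.approx(0.3466, abs=1e-3)
        assert not res.significant

    def test_identical_samples(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_single_element_sample_errors(self):
        with pytest.raises(ValueError, match="n >= 2"):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 10, 40)
        pooled = two_sample_ttest(a, b, "pooled")
        welch = two_sample_ttest(a, b, "welch")
        assert pooled.t != welch.t

    def test_unknown_variant_errors(self):
        with pytest.raises(ValueError, match="variant"):
            two_sample_ttest([1, 2], [3, 4], "bayes")

    def test_type_one_error_calibrated_at_five_percent(self):
        """Null cohorts at the study's group sizes (8 vs 21): rejection
        rate over 5000 seeded replicates is 5% +/- 1%."""
        rng = np.random.default_rng(2024)
        n_rep = 5000
        a = rng.normal(0.0, 1.0, (n_rep, 8))
        b = rng.normal(0.0, 1.0, (n_rep, 21))
        rejections = sum(
            two_sample_ttest(a[i], b[i]).significant for i in range(n_rep)
        )
        rate = rejections / n_rep
        assert 0.04 <= rate <= 0.06


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = univariate_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_slope_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        beta, sigma, n = 0.7, 2.0, 200
        x = rng.uniform(0, 10, n)
        y = beta * x + rng.normal(0, sigma, n)
        res = univariate_regression(x, y)
        assert abs(res.slope - beta) < 3 * res.slope_se

    def test_confidence_band_brackets_fit(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 30)
        y = x + rng.normal(0, 0.1, 30)
        res = univariate_regression(x, y)
        fit, lo, hi = res.ci_band(np.linspace(0, 1, 7))
        assert np.all(lo < fit) and np.all(fit < hi)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            univariate_regression(np.ones(5), np.arange(5.0))

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            univariate_regression([1, 2], [1, 2])

    def test_leverage_point_drives_significance(self):
        """A null cloud plus one extreme point: the association is
        significant only while that point is included; the leave-one-out
        report flags exactly it."""
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.uniform(0, 1, 15), [8.0]])
        y = np.concatenate([rng.normal(0, 1.0, 15), [9.0]])
        res = univariate_regression(x, y)
        assert res.significant
        loo = res.leave_one_out(x, y)
        flipped = loo[loo["flips_significance"]]
        assert list(flipped["excluded"]) == [15]


def _toy_cohort(n_control=5, n_af=7, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_control):
        rows.append(
            {"subject_id": f"c{i}", "group": "control",
             "la_ef": rng.normal(53, 7),
             "rt_la_with_laa": rng.normal(0.7, 0.15),
             "rt_la_without_laa": rng.normal(0.65, 0.15),
             "rt_laa": rng.normal(1.8, 0.4),
             "laa_shape_label": "chicken_wing"}
        )
    for i in range(n_af):
        rows.append(
            {"subject_id": f"a{i}", "group": "af",
             "la_ef": rng.normal(43, 9),
             "rt_la_with_laa": rng.normal(0.7 + delta, 0.15),
             "rt_la_without_laa": rng.normal(0.65 + delta, 0.15),
             "rt_laa": rng.normal(1.8 + delta, 0.4),
             "laa_shape_label": "chicken_wing" if i % 3 else "non_chicken_wing"}
        )
    return pd.DataFrame(rows)


class TestGroupSummary:
    def test_identical_groups_all_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(8)],
                "group": ["control"] * 4 + ["af"] * 4,
                "metric": vals + vals,
            }
        )
        out = group_summary(table, fields=["metric"])
        assert out.loc["metric", "p_value"] == pytest.approx(1.0)
        assert not out.loc["metric", "significant"]

    def test_missing_field_names_subject_and_field(self):
        table = _toy_cohort()
        table.loc[2, "la_ef"] = np.nan
        with pytest.raises(ValueError, match="c2.*la_ef"):
            group_summary(table, fields=["la_ef"])

    def test_empty_group_errors(self):
        table = _toy_cohort(n_control=0)
        with pytest.raises(ValueError, match="empty group"):
            group_summary(table, fields=["la_ef"])


class TestShapeSubgroups:
    def test_single_label_is_descriptive_only(self):
        table = _toy_cohort()
        table["laa_shape_label"] = "chicken_wing"
        out = shape_subgroup_analysis(table)
        assert out["p_value"].isna().all()

    def test_n1_subgroup_emits_no_p_value(self):
        table = _toy_cohort(n_af=0, n_control=5)
        table.loc[0, "laa_shape_label"] = "non_chicken_wing"
        out = shape_subgroup_analysis(table)
        assert out[out["group"] == "control"]["p_value"].isna().all()

    def test_null_split_p_values_roughly_uniform(self):
        """16/5 label split with identical residence-time distributions:
        the rejection fraction stays near the nominal 5% level."""
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(21)],
                    "group": ["af"] * 21,
                    "rt_laa": rng.normal(2.8, 0.6, 21),
                    "rt_la_with_laa": rng.normal(1.2, 0.3, 21),
                    "rt_la_without_laa": rng.normal(1.1, 0.3, 21),
                    "laa_shape_label": ["chicken_wing"] * 16
                    + ["non_chicken_wing"] * 5,
                }
            )
            out = shape_subgroup_analysis(table)
            p = out.loc[out["field"] == "rt_laa", "p_value"].iloc[0]
            hits += p < 0.05
        assert 0.02 <= hits / n_seeds <= 0.09

    def test_pipeline_table_round_trip(self):
        out = shape_subgroup_analysis(_toy_cohort())
        assert set(out["group"]) == {"control", "af"}


class TestCohortTable:
    def test_duplicate_ids_rejected(self):
        table = _toy_cohort()
        table.loc[1, "subject_id"] = "c0"
        with pytest.raises(ValueError, match="duplicate"):
            validate_cohort_table(table)

    def test_unknown_group_rejected(self):
        table = _toy_cohort()
        table.loc[0, "group"] = "patient"
        with pytest.raises(ValueError, match="group"):
            validate_cohort_table(table)
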