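"""Rank tests, Kaplan-Meier/log-rank and Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    benjamini_hochberg,
    cox_ph,
    feature_vs_clinical_tests,
    km_logrank,
    logrank_pvalue,
    multivariable_report,
)


def _exp_cohort(rng, n_per_arm, hr=1.0, base=0.05, cens=0.02):
    n = 2 * n_per_arm
    arm = np.repeat([0, 1], n_per_arm)
    t = rng.exponential(1.0 / (base * np.where(arm == 1, hr, 1.0)))
    c = rng.exponential(1.0 / cens, n)
    return pd.DataFrame({"arm": arm.astype(float),
                         "os_months": np.minimum(t, c),
                         "os_event": (t <= c).astype(int)})


class TestFeatureVsClinical:
    def test_identical_groups_give_large_p(self):
        df = pd.DataFrame({"smoker": [0] * 10 + [1] * 10,
                           "score": list(range(10)) * 2})
        out = feature_vs_clinical_tests(df, "smoker", ["score"])
        assert out["p"].iloc[0] >= 0.95

    def test_two_levels_route_to_rank_sum_three_to_kruskal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"two": np.repeat([0, 1], 20),
                           "three": np.tile([0, 1, 2], 14)[:40],
                           "score": rng.normal(size=40)})
        assert feature_vs_clinical_tests(df, "two", ["score"])["test"].iloc[0] \
            == "wilcoxon_rank_sum"
        assert feature_vs_clinical_tests(df, "three", ["score"])["test"].iloc[0] \
            == "kruskal_wallis"

    def test_shifted_scores_detected(self):
        """A +15 score shift at n=100/arm is detected at p<0.01 in >=19/20
        replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            df = pd.DataFrame({
                "smoker": np.repeat([0, 1], 100),
                "score": np.concatenate([rng.normal(0, 10, 100),
                                         rng.normal(15, 10, 100)])})
            out = feature_vs_clinical_tests(df, "smoker", ["score"])
            hits += out["p"].iloc[0] < 0.01
        assert hits >= 19

    def test_constant_feature_skipped(self):
        df = pd.DataFrame({"smoker": [0, 0, 1, 1], "score": [3.0] * 4})
        assert feature_vs_clinical_tests(df, "smoker", ["score"]).empty

    def test_rank_tests_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"g": np.repeat([0, 1], 30),
                           "score": rng.normal(size=60)})
        p1 = feature_vs_clinical_tests(df, "g", ["score"])["p"].iloc[0]
        df["score"] = np.exp(df["score"])
        p2 = feature_vs_clinical_tests(df, "g", ["score"])["p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_benjamini_hochberg_bounds(self):
        p = np.array([0.001, 0.01, 0.4, 0.9])
        adj = benjamini_hochberg(p)
        assert (adj >= p).all() and (adj <= 1).all()


class TestKMLogrank:
    def test_identical_arms_statistic_zero(self):
        t = [3.0, 5.0, 8.0, 12.0]
        e = [1, 1, 0, 1]
        res = km_logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.logrank_p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(10)
        df = _exp_cohort(rng, 50, hr=1.8)
        arm = np.where(df["arm"] == 1, "x", "y")
        p1 = logrank_pvalue(df["os_months"], df["os_event"], arm)
        p2 = logrank_pvalue(df["os_months"], df["os_event"],
                            np.where(arm == "x", "y", "x"))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_km_estimates_are_nonincreasing_step_functions(self):
        rng = np.random.default_rng(11)
        df = _exp_cohort(rng, 40)
        res = km_logrank(df["os_months"], df["os_event"], df["arm"])
        for kmf in res.fits.values():
            surv = kmf.survival_function_.iloc[:, 0].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert surv[0] == 1.0 and (surv >= 0).all()

    def test_doubled_hazard_detected(self):
        """HR=2 at n=200/arm gives log-rank p<0.05 in >=18/20 replicates."""
        rng = np.random.default_rng(12)
        hits = sum(
            logrank_pvalue(df["os_months"], df["os_event"], df["arm"]) < 0.05
            for df in (_exp_cohort(rng, 200, hr=2.0) for _ in range(20)))
        assert hits >= 18

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestCoxPH:
    def test_constant_covariate_rejected(self):
        df = _exp_cohort(np.random.default_rng(1), 20)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_ph(df, ["flat"])

    def test_true_hazard_ratio_recovered(self):
        rng = np.random.default_rng(2)
        df = _exp_cohort(rng, 250, hr=2.0)
        fit = cox_ph(df, ["arm"])
        assert 1.6 < fit.hr("arm") < 2.5
        assert fit.table.loc["arm", "CI_lower"] < fit.hr("arm") \
            < fit.table.loc["arm", "CI_upper"]

    def test_wald_statistic_definition(self):
        df = _exp_cohort(np.random.default_rng(4), 100, hr=1.5)
        fit = cox_ph(df, ["arm"])
        row = fit.table.loc["arm"]
        assert row["Wald"] == pytest.approx((row["B"] / row["SE"]) ** 2)
        assert row["HR"] == pytest.approx(np.exp(row["B"]))

    def test_collinear_covariate_dropped_with_warning(self):
        df = _exp_cohort(np.random.default_rng(5), 50, hr=1.5)
        df["arm_copy"] = df["arm"]
        with pytest.warns(UserWarning, match="collinear"):
            fit = cox_ph(df, ["arm", "arm_copy"])
        assert list(fit.table.index) == ["arm"]

    def test_separation_flagged(self):
        # events only in one covariate level: partial likelihood diverges
        df = pd.DataFrame({
            "x": np.repeat([0.0, 1.0], 20),
            "os_months": np.concatenate([np.full(20, 50.0),
                                         np.linspace(1, 10, 20)]),
            "os_event": np.repeat([0, 1], 20)})
        with pytest.warns(UserWarning, match="separation"):
            fit = cox_ph(df, ["x"])
        assert fit.flags

    def test_multivariable_reduces_to_clinical_only_without_spatial_features(self):
        rng = np.random.default_rng(6)
        df = _exp_cohort(rng, 100, hr=1.8)
        df["smoker"] = rng.integers(0, 2, len(df)).astype(float)
        direct = cox_ph(df, ["arm", "smoker"])
        report = multivariable_report(df, spatial_features=[],
                                      clinical_adjusters=["arm", "smoker"])
        pd.testing.assert_frame_equal(report.table, direct.table)

    def test_log_hr_bias_shrinks_with_n(self):
        rng = np.random.default_rng(8)
        true = np.log(2.0)
        bias = {}
        for n in (100, 500):
            est = [cox_ph(_exp_cohort(rng, n, hr=2.0), ["arm"])
                   .table.loc["arm", "B"] for _ in range(15)]
            bias[n] = abs(np.mean(est) - true)
        assert bias[500] < bias[100] + 0.05  # noise guard; large-n no worse
        assert bias[500] < 0.15
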