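"""t-test machinery, compliance rules and exploratory correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronofood.trial_outcomes import (
    between_group_difference,
    classify_compliance,
    explore_weight_predictors,
    mann_whitney,
    paired_change_test,
    trial_summary,
)


class TestPairedTest:
    def test_identical_samples(self):
        res = paired_change_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_shift_degenerate(self):
        res = paired_change_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.mean_change == 1.0
        assert math.isnan(res.t)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_change_test([1.0, 2.0], [1.0])

    def test_matches_first_principles_and_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            pre = rng.normal(80, 10, n)
            post = pre + rng.normal(-1, 2, n)
            res = paired_change_test(pre, post)
            d = post - pre
            t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p_manual = 2 * stats.t.sf(abs(t_manual), n - 1)
            assert res.t == pytest.approx(t_manual)
            assert res.p == pytest.approx(p_manual)
            sp = stats.ttest_rel(post, pre)
            assert res.t == pytest.approx(sp.statistic)
            assert res.p == pytest.approx(sp.pvalue)


class TestBetweenGroup:
    def test_identical_groups(self):
        res = between_group_difference([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.difference == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_student_and_welch(self):
        rng = np.random.default_rng(1)
        for equal_var in (True, False):
            a = rng.normal(0, 3, 25)
            b = rng.normal(-1, 2, 20)
            res = between_group_difference(a, b, equal_var=equal_var)
            sp = stats.ttest_ind(a, b, equal_var=equal_var)
            assert res.t == pytest.approx(sp.statistic)
            assert res.p == pytest.approx(sp.pvalue)

    def test_ci_from_first_principles(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 3, 25), rng.normal(-1, 3, 20)
        res = between_group_difference(a, b)
        na, nb = 25, 20
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        crit = stats.t.ppf(0.975, na + nb - 2)
        diff = a.mean() - b.mean()
        assert res.ci_low == pytest.approx(diff - crit * se)
        assert res.ci_high == pytest.approx(diff + crit * se)
        assert res.ci_low < res.difference < res.ci_high

    def test_simulation_recovers_true_difference(self):
        """Two arms with a true -1 difference, estimated without bias."""
        rng = np.random.default_rng(3)
        diffs = []
        for _ in range(1000):
            a = rng.normal(-1.0, 3.0, 25)
            b = rng.normal(0.0, 3.0, 20)
            diffs.append(between_group_difference(a, b).difference)
        assert np.mean(diffs) == pytest.approx(-1.0, abs=0.1)

    def test_mann_whitney_available(self):
        rng = np.random.default_rng(4)
        u, p = mann_whitney(rng.normal(0, 1, 20), rng.normal(1, 1, 20))
        sp = stats.mannwhitneyu(
            rng.normal(0, 1, 20), rng.normal(1, 1, 20), alternative="two-sided"
        )
        assert 0 <= p <= 1 and u >= 0


class TestCompliance:
    def test_sda_direction_rules(self):
        rep = classify_compliance("P0", "SDA", d_nova1_pp=7.0, d_nova4_pp=-7.6)
        assert rep.compliant is True

    def test_sda_boundaries_strict(self):
        assert classify_compliance("P0", "SDA", 0.0, 0.0).compliant is False
        assert classify_compliance("P0", "SDA", 1.0, 0.0).compliant is False
        assert classify_compliance("P0", "SDA", 0.0, -1.0).compliant is False

    def test_tre_duration_rule(self):
        assert classify_compliance("P0", "TRE", intervention_duration=11.5).compliant is True
        assert classify_compliance("P0", "TRE", intervention_duration=12.0).compliant is True
        assert classify_compliance("P0", "TRE", intervention_duration=12.1).compliant is False

    def test_missing_data_undetermined(self):
        assert classify_compliance("P0", "SDA").compliant is None
        assert classify_compliance("P0", "TRE").compliant is None

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            classify_compliance("P0", "CONTROL")


class TestTrialSummary:
    def test_weight_reported_as_percent_change(self):
        pre = pd.DataFrame({"weight": [80.0, 90.0, 70.0, 100.0]}, index=list("abcd"))
        post = pd.DataFrame({"weight": [78.4, 88.2, 70.0, 99.0]}, index=list("abcd"))
        arms = {"a": "TRE", "b": "TRE", "c": "SDA", "d": "SDA"}
        tbl = trial_summary(pre, post, arms)
        tre = tbl[(tbl.outcome == "weight") & (tbl.arm == "TRE")].iloc[0]
        assert tre["change_mean"] == pytest.approx((-2.0 - 2.0) / 2)
        assert tre["percent_change"]

    def test_between_diff_is_tre_minus_sda(self, small_cohort):
        pre = small_cohort.outcomes.set_index("participant_id")
        post = small_cohort.outcomes_post.set_index("participant_id")
        arms = dict(
            zip(small_cohort.participants.participant_id, small_cohort.participants.arm)
        )
        tbl = trial_summary(pre, post, arms, outcomes=["weight"])
        tre_chg = tbl[tbl.arm == "TRE"]["change_mean"].iloc[0]
        sda_chg = tbl[tbl.arm == "SDA"]["change_mean"].iloc[0]
        assert tbl["between_diff"].iloc[0] == pytest.approx(tre_chg - sda_chg, abs=1e-9)


class TestWeightPredictors:
    def test_self_correlation_is_one(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        covs = pd.DataFrame({"x": y})
        res = explore_weight_predictors(y, covs)
        assert res["rho"].iloc[0] == pytest.approx(1.0)

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=25))
        covs = pd.DataFrame({"x": rng.normal(size=25), "neg_x": 0.0})
        covs["neg_x"] = -covs["x"]
        res = explore_weight_predictors(y, covs).set_index("covariate")
        assert res.loc["x", "rho"] == pytest.approx(-res.loc["neg_x", "rho"])

    def test_null_covariate_respects_critical_value(self):
        """Under independence, |rho| exceeds the two-sided 5% critical value
        for n=25 (0.396) in about 5% of replicates."""
        rng = np.random.default_rng(6)
        exceed = 0
        reps = 1000
        for _ in range(reps):
            r = stats.pearsonr(rng.normal(size=25), rng.normal(size=25))[0]
            exceed += abs(r) > 0.396
        assert 0.02 <= exceed / reps <= 0.08

    def test_zero_variance_reported_missing(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        covs = pd.DataFrame({"flat": [5.0, 5.0, 5.0]}, index=list("abc"))
        res = explore_weight_predictors(y, covs)
        assert math.isnan(res["rho"].iloc[0])

    def test_sex_handled_as_two_sample_comparison(self):
        rng = np.random.default_rng(7)
        idx = [f"p{i}" for i in range(20)]
        y = pd.Series(rng.normal(size=20), index=idx)
        covs = pd.DataFrame({"sex": ["female"] * 10 + ["male"] * 10}, index=idx)
        res = explore_weight_predictors(y, covs)
        assert res["kind"].iloc[0] == "two_sample"
        assert 0 <= res["p"].iloc[0] <= 1
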