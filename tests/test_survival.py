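"""Kaplan-Meier, log-rank, and Cox fits against hand/brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import immusub as im
from immusub.consensus import SubtypeLabels
from immusub.containers import SurvivalData


def surv_table(times, events, **covs):
    idx = [f"s{i}" for i in range(len(times))]
    return SurvivalData(
        pd.DataFrame({"time": times, "event": events, **covs}, index=idx)
    )


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = im.km_estimate(surv_table([5.0, 6.0, 7.0], [0, 0, 0]))
        assert km.all_censored
        assert len(km.event_times) == 0

    def test_all_events_product_limit(self):
        km = im.km_estimate(surv_table([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_interleaved_censoring_hand_fixture(self):
        """Six subjects, events at 1,3,4,6 with censoring at 2 and 5:
        S = 5/6, 5/8, 5/12, 0 (hand product-limit computation)."""
        km = im.km_estimate(surv_table([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1]))
        assert np.array_equal(km.event_times, [1, 3, 4, 6])
        assert np.allclose(km.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
        assert np.array_equal(km.at_risk, [6, 4, 3, 1])

    def test_tail_censor_times_beyond_last_event_are_irrelevant(self):
        """Where exactly the tail subjects are censored (past the last event)
        does not affect the product-limit curve."""
        k1 = im.km_estimate(surv_table([1, 2, 3, 4, 5], [1, 1, 1, 0, 0]))
        k2 = im.km_estimate(surv_table([1, 2, 3, 40, 99], [1, 1, 1, 0, 0]))
        assert np.array_equal(k1.event_times, k2.event_times)
        assert np.allclose(k1.survival, k2.survival)

    def test_grouped_curves(self):
        data = surv_table([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"], index=data.sample_ids)
        curves = im.km_estimate(data, groups)
        assert set(curves) == {"a", "b"}
        assert np.allclose(curves["a"].survival, [0.5, 0.0])


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 0, 1, 1] * 2
        data = surv_table(times, events)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=data.sample_ids)
        stat, df, p = im.logrank_test(data, groups)
        assert abs(stat) < 1e-12
        assert df == 1
        assert p > 0.999

    def test_hand_table_fixture(self):
        """n=8 two-group fixture checked against a step-by-step O-E/V
        computation done inline with the textbook hypergeometric variance."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        grp = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        data = surv_table(times, events)
        stat, df, p = im.logrank_test(
            data, pd.Series(grp, index=data.sample_ids)
        )

        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n_tot, n_1 = at_risk.sum(), (at_risk & (grp == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d_1 = ((times == t) & (events == 1) & (grp == 1)).sum()
            o_minus_e += d_1 - d * n_1 / n_tot
            if n_tot > 1:
                var += d * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d) / (n_tot - 1)
        assert np.isclose(stat, o_minus_e**2 / var)

    @staticmethod
    def plain_logrank_stat(times, events, grp):
        """Direct O-E/V two-group log-rank, independent of lifelines."""
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            n_tot = at_risk.sum()
            n_1 = (at_risk & (grp == 1)).sum()
            d = ((times == t) & (events == 1)).sum()
            d_1 = ((times == t) & (events == 1) & (grp == 1)).sum()
            o_minus_e += d_1 - d * n_1 / n_tot
            if n_tot > 1:
                var += d * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d) / (n_tot - 1)
        return o_minus_e**2 / var

    def test_asymptotic_p_matches_permutation_oracle(self):
        """n=20 two-group data: chi-square p within 3 sigma Monte-Carlo error
        of a 5000-permutation reference distribution of the statistic."""
        rng = np.random.default_rng(7)
        n = 20
        grp = np.array([0] * 10 + [1] * 10)
        t_ev = rng.exponential(30 * np.where(grp == 1, 0.5, 1.0))
        t_c = rng.uniform(0, 60, n)
        times = np.minimum(t_ev, t_c)
        events = (t_ev <= t_c).astype(int)
        data = surv_table(times, events)
        stat, _, p = im.logrank_test(data, pd.Series(grp, index=data.sample_ids))
        assert np.isclose(stat, self.plain_logrank_stat(times, events, grp))

        n_perm = 5000
        perm_stats = np.array(
            [
                self.plain_logrank_stat(times, events, rng.permutation(grp))
                for _ in range(n_perm)
            ]
        )
        p_perm = (perm_stats >= stat - 1e-12).mean()
        mc_sd = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) <= 3 * mc_sd + 0.01

    def test_single_group_rejected(self):
        data = surv_table([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            im.logrank_test(data, pd.Series(["a", "a"], index=data.sample_ids))


class TestCox:
    def ten_subjects(self):
        times = [2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0, 11.0, 12.0]
        events = [1, 1, 1, 0, 1, 1, 0, 1, 1, 0]
        x = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        return surv_table(times, events, x=x), np.array(times), np.array(events), np.array(x)

    @staticmethod
    def efron_neg_pl(beta, times, events, x):
        """Independent Efron partial log-likelihood (direct summation)."""
        ll = 0.0
        for t in np.unique(times[events == 1]):
            D = np.flatnonzero((times == t) & (events == 1))
            R = np.flatnonzero(times >= t)
            d = len(D)
            sum_r = np.exp(beta * x[R]).sum()
            sum_d = np.exp(beta * x[D]).sum()
            ll += beta * x[D].sum()
            for j in range(d):
                ll -= np.log(sum_r - (j / d) * sum_d)
        return -ll

    def test_loghr_matches_brute_force_efron(self):
        data, times, events, x = self.ten_subjects()
        fit = im.cox_fit(data, ["x"], ties="efron")
        res = minimize_scalar(
            self.efron_neg_pl, bounds=(-5, 5), method="bounded",
            args=(times, events, x), options={"xatol": 1e-12},
        )
        assert abs(fit.summary.loc["x", "log_hr"] - res.x) < 1e-6

    def test_hr_and_ci_consistency(self):
        data, *_ = self.ten_subjects()
        row = im.cox_fit(data, ["x"]).summary.loc["x"]
        assert np.isclose(row.hr, np.exp(row.log_hr))
        assert np.isclose(row.ci_low, np.exp(row.log_hr - 1.96 * row.se), rtol=1e-3)

    def test_sign_flips_with_coding(self):
        data, times, events, x = self.ten_subjects()
        flipped = surv_table(times, events, x=1.0 - x)
        b1 = im.cox_fit(data, ["x"]).summary.loc["x", "log_hr"]
        b2 = im.cox_fit(flipped, ["x"]).summary.loc["x", "log_hr"]
        assert np.isclose(b1, -b2, atol=1e-6)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(8)
        times = rng.uniform(1, 50, 30)  # continuous -> no ties
        events = rng.integers(0, 2, 30)
        events[0] = 1
        x = rng.normal(size=30)
        data = surv_table(times, events, x=x)
        b_e = im.cox_fit(data, ["x"], ties="efron").summary.loc["x", "log_hr"]
        b_b = im.cox_fit(data, ["x"], ties="breslow").summary.loc["x", "log_hr"]
        assert np.isclose(b_e, b_b, atol=1e-6)

    def test_categorical_needs_declared_baseline(self):
        data = surv_table([1, 2, 3, 4], [1, 1, 1, 0], stage=["III", "IV", "III", "IV"])
        with pytest.raises(ValueError, match="baseline"):
            im.cox_fit(data, ["stage"])
        data.baselines["stage"] = "III"
        fit = im.cox_fit(data, ["stage"])
        assert "stage[IV]" in fit.summary.index

    def test_reciprocal_hr_when_baseline_swapped(self):
        rng = np.random.default_rng(9)
        n = 60
        lv = np.where(rng.uniform(size=n) < 0.5, "A", "B")
        t = rng.exponential(20 * np.where(lv == "A", 1.0, 0.6))
        c = rng.uniform(0, 40, n)
        data = surv_table(np.minimum(t, c), (t <= c).astype(int), grp=lv)
        data.baselines["grp"] = "A"
        hr_ba = im.cox_fit(data, ["grp"]).summary.loc["grp[B]", "hr"]
        data.baselines["grp"] = "B"
        hr_ab = im.cox_fit(data, ["grp"]).summary.loc["grp[A]", "hr"]
        assert np.isclose(hr_ba, 1 / hr_ab, rtol=1e-5)

    def test_null_covariate_rarely_significant(self):
        """Covariate independent of survival: |logHR| < 2 SE in >= 90% of
        replicates (n=300 each)."""
        rng = np.random.default_rng(10)
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(30, n)
            c = rng.uniform(0, 60, n)
            data = surv_table(np.minimum(t, c), (t <= c).astype(int), x=x)
            row = im.cox_fit(data, ["x"]).summary.loc["x"]
            ok += abs(row.log_hr) < 2 * row.se
        assert ok >= 0.90 * n_rep


class TestSubtypeReport:
    def test_planted_contrast_detected(self, study, label_map):
        report = im.subtype_survival_report(
            study.clinical, study.subtypes, adjust=("cohort",)
        )
        pair = report["pairwise_logrank"]
        assert label_map[pair["worst"]] == "IS4"  # planted worst prognosis
        cox = report["cox"]
        best_term = f"subtype[{pair['best']}]"
        assert cox.summary.loc[best_term, "hr"] < 1.0

    def test_single_subtype_skips_logrank(self, study):
        one = SubtypeLabels(
            pd.Series("IS1", index=study.clinical.sample_ids), provenance="discovery"
        )
        report = im.subtype_survival_report(study.clinical, one)
        assert report["overall_logrank"] is None
        assert "IS1" in report["km"]
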