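import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank

from stemscore.io import ClinicalTable
from stemscore.survival import (
    km_estimate,
    logrank_test,
    multivariate_logistic,
    restrict_outcome_subset,
    survival_at,
)


def brute_km(times, events):
    """Independent product-limit: explicit risk sets, explicit products."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    s, out = 1.0, {}
    for t in sorted(set(times[events == 1])):
        n_at = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at
        out[t] = s
    return out


def brute_logrank_chi2(times, events, group1):
    """Independent log-rank: per-event-time 2x2 hypergeometric tables."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    group1 = np.asarray(group1, bool)
    o = e = v = 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n, n1 = at.sum(), (at & group1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group1).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


class TestKaplanMeier:
    def test_single_subject_event(self):
        curve = km_estimate([5.0], [1])
        assert survival_at(curve, 4.9).estimate == 1.0
        assert survival_at(curve, 5.0).estimate == 0.0

    def test_all_censored_curve_stays_at_one(self):
        with pytest.raises(ValueError):
            # log-rank needs events; KM itself is fine:
            logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.event_times.size == 0
        assert survival_at(curve, 2.5).estimate == 1.0

    def test_toy_product_limit_values(self):
        # (1 event, 2 censored, 3 event): S(1)=2/3, S(3)=0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 1])

    def test_no_censoring_equals_empirical_survivor_function(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(2.0, size=40).round(1)  # rounding forces ties
        curve = km_estimate(times, np.ones_like(times, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_brute_force_product_limit_with_censoring(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(2.0, size=60).round(1)
        events = rng.integers(0, 2, size=60)
        curve = km_estimate(times, events)
        expected = brute_km(times, events)
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(expected[t], abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


class TestSurvivalAt:
    def test_at_time_zero_and_before_first_event(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        at0 = survival_at(curve, 0.0)
        assert (at0.estimate, at0.ci_lower, at0.ci_upper) == (1.0, 1.0, 1.0)
        assert survival_at(curve, 0.5).estimate == 1.0

    def test_greenwood_variance_closed_form_on_toy(self):
        # at t=2: S=2/3, var = S^2 * d/(n(n-d)) = (4/9) * 1/6
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.greenwood_var[0] == pytest.approx((4 / 9) * (1 / 6), abs=1e-12)
        at2 = survival_at(curve, 2.0)
        assert at2.estimate == pytest.approx(2 / 3)
        assert 0.0 <= at2.ci_lower < at2.estimate < at2.ci_upper <= 1.0
        assert not at2.extrapolated

    def test_loglog_interval_matches_direct_evaluation(self):
        rng = np.random.default_rng(8)
        times = rng.exponential(3.0, 50)
        events = rng.integers(0, 2, 50)
        curve = km_estimate(times, events)
        t = float(np.median(times))
        at = survival_at(curve, t, conf=0.95)
        idx = np.searchsorted(curve.event_times, t, side="right") - 1
        s, var = curve.survival[idx], curve.greenwood_var[idx]
        se = np.sqrt(var) / (s * abs(np.log(s)))
        assert at.ci_lower == pytest.approx(s ** np.exp(1.959963984540054 * se))
        assert at.ci_upper == pytest.approx(s ** np.exp(-1.959963984540054 * se))

    def test_extrapolation_flagged(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert survival_at(curve, 10.0).extrapolated
        assert not survival_at(curve, 3.0).extrapolated


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        result = logrank_test(times, events, groups)
        assert result.chi2 == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_separated_groups_match_brute_force(self):
        times = np.array([1.0] * 5 + [10.0] * 5)
        events = np.ones(10, dtype=int)
        groups = np.array(["A"] * 5 + ["B"] * 5)
        result = logrank_test(times, events, groups)
        assert result.chi2 == pytest.approx(
            brute_logrank_chi2(times, events, groups == "A"), abs=1e-12
        )
        assert sum(result.observed) == events.sum()

    def test_random_instances_match_brute_force_and_lifelines(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            times = rng.exponential(2.0, n).round(1)
            events = rng.integers(0, 2, n)
            groups = rng.integers(0, 2, n)
            if events.sum() == 0 or len(np.unique(groups)) < 2:
                continue
            result = logrank_test(times, events, groups)
            assert result.chi2 == pytest.approx(
                brute_logrank_chi2(times, events, groups == 0), abs=1e-10
            )
            ll = lifelines_logrank(
                times[groups == 0], times[groups == 1],
                events[groups == 0], events[groups == 1],
            )
            assert result.chi2 == pytest.approx(ll.test_statistic, abs=1e-8)
            assert result.p == pytest.approx(ll.p_value, abs=1e-10)

    def test_invariant_to_label_swap_and_monotone_time_transform(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(1.0, 40)
        events = rng.integers(0, 2, 40)
        groups = rng.integers(0, 2, 40)
        base = logrank_test(times, events, groups)
        swapped = logrank_test(times, events, 1 - groups)
        warped = logrank_test(np.log1p(times) ** 2, events, groups)
        assert swapped.chi2 == pytest.approx(base.chi2, abs=1e-12)
        assert warped.chi2 == pytest.approx(base.chi2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestOutcomeRestriction:
    def _clinical(self, rows):
        return ClinicalTable(
            pd.DataFrame(
                rows,
                columns=["sample_id", "os_time", "os_event"],
            ).assign(
                mycn_amplified=pd.array([None] * len(rows), dtype="Int64"),
                stage4=pd.array([None] * len(rows), dtype="Int64"),
                age_ge_1y=pd.array([None] * len(rows), dtype="Int64"),
            )
        )

    def test_rule_keeps_deaths_and_long_survivors(self):
        clin = self._clinical(
            [["short_censor", 2.0, 0], ["early_death", 1.0, 1], ["long_survivor", 5.0, 0]]
        )
        outcome, kept = restrict_outcome_subset(clin, min_followup=3.0)
        assert kept == ["early_death", "long_survivor"]
        np.testing.assert_array_equal(outcome, [1, 0])

    def test_empty_subset_rejected(self):
        clin = self._clinical([["a", 1.0, 0], ["b", 2.0, 0]])
        with pytest.raises(ValueError):
            restrict_outcome_subset(clin, min_followup=3.0)


class TestLogistic:
    def test_single_binary_covariate_reproduces_contingency_odds_ratio(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-0.3 + 0.9 * x)))).astype(int)
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        fit = multivariate_logistic(y, pd.DataFrame({"x": x}))
        assert fit.converged and not fit.separation
        assert fit.odds_ratio("x") == pytest.approx(a * d / (b * c), abs=1e-6)

    def test_null_covariate_odds_ratio_near_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        x = rng.normal(size=500)  # independent of outcome
        fit = multivariate_logistic(y, pd.DataFrame({"x": x}))
        assert 0.8 <= fit.odds_ratio("x") <= 1.25
        assert fit.p_value("x") > 0.05

    def test_perfect_separation_flagged_not_raised(self):
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        fit = multivariate_logistic(x, pd.DataFrame({"x": x}))
        assert fit.separation and not fit.converged

    def test_missing_covariates_excluded(self):
        y = np.array([0, 1, 0, 1, 0, 1])
        covs = pd.DataFrame(
            {"x": [0.1, 1.2, 0.3, 1.4, np.nan, 0.9], "z": [1, 0, 1, 0, 1, 0]}
        )
        fit = multivariate_logistic(y, covs)
        assert (fit.n_used, fit.n_excluded) == (5, 1)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            multivariate_logistic(np.ones(6), pd.DataFrame({"x": np.arange(6.0)}))

    def test_constant_covariate_rejected(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="constant"):
            multivariate_logistic(y, pd.DataFrame({"x": [2.0, 2.0, 2.0, 2.0]}))
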