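"""Survival statistics: product-limit estimate against hand and brute-force
oracles, log-rank fixtures and symmetry, Cox parameter recovery/calibration,
and the score-test identity with the log-rank statistic."""

import numpy as np
import pandas as pd
import pytest

from ferroscore.io import SurvivalTable
from ferroscore.simulate import simulate_survival
from ferroscore.survival import (cox_score_test, cox_univariate, kaplan_meier,
                                 logrank_test, logrank_test_table)


def brute_force_km(time, event):
    """Counting-process product-limit: loop over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        curve = kaplan_meier(np.array([1.0, 2.0, 3.0]), event=np.array([1, 1, 1]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_no_events_curve_constant_one(self):
        with pytest.warns(UserWarning, match="censored"):
            curve = kaplan_meier(np.array([1.0, 2.0]), event=np.array([0, 0]))
        assert curve.survival_at(5.0) == 1.0

    def test_censored_tail_does_not_enter_the_product(self):
        # moving a censoring time beyond the last event changes nothing
        c1 = kaplan_meier(np.array([1.0, 2.0, 3.0, 9.0]),
                          event=np.array([1, 1, 1, 0]))
        c2 = kaplan_meier(np.array([1.0, 2.0, 3.0, 100.0]),
                          event=np.array([1, 1, 1, 0]))
        np.testing.assert_allclose(c1.survival, c2.survival)
        np.testing.assert_allclose(c1.times, c2.times)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            time = np.round(rng.exponential(5.0, n), 1) + 0.1
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            curve = kaplan_meier(time, event=event)
            bt, bs = brute_force_km(time, event)
            np.testing.assert_allclose(curve.times, bt)
            np.testing.assert_allclose(curve.survival, bs, atol=1e-12)

    def test_greenwood_variance_nonnegative_and_survival_monotone(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(5.0, 80)
        event = rng.integers(0, 2, 80)
        event[0] = 1
        curve = kaplan_meier(time, event=event)
        assert (curve.variance >= 0).all()
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival_at(-1.0) == 1.0


class TestLogrank:
    def test_hand_derived_four_subject_fixture(self):
        chi2, p = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)  # (O-E)=7/6, V=17/36
        assert 0 < p < 1

    def test_identical_strata_chi2_zero(self):
        chi2, _ = logrank_test([1, 2, 1, 2], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(3.0, 40)
        e = rng.integers(0, 2, 40)
        e[:2] = 1
        g = rng.integers(0, 2, 40)
        chi2a, _ = logrank_test(t, e, g)
        chi2b, _ = logrank_test(t, e, 1 - g)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["A", "A"])

    def test_table_wrapper_aligns_by_sample(self):
        table = SurvivalTable(pd.DataFrame({
            "sample": ["a", "b", "c", "d"], "time": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1]}))
        strata = pd.Series(["A", "A", "B", "B"], index=["a", "b", "c", "d"])
        chi2, _ = logrank_test_table(table, strata)
        assert chi2 == pytest.approx(49 / 17, abs=1e-9)


class TestCox:
    def test_binary_beta_half_recovered_with_coverage(self):
        estimates, covered = [], 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            scores = pd.Series(rng.integers(0, 2, 500).astype(float),
                               index=[f"p{i}" for i in range(500)])
            table, _ = simulate_survival(scores, beta=0.5, lambda0=0.1,
                                         censor_rate=0.2, seed=2000 + rep)
            res = cox_univariate(table, covariate="score")
            estimates.append(res.beta)
            covered += res.ci_low <= np.exp(0.5) <= res.ci_high
        assert abs(np.mean(estimates) - 0.5) <= 0.15
        assert covered / 100 >= 0.90

    def test_null_covariate_calibrated_type_i(self):
        rejections = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            scores = pd.Series(rng.normal(0, 1, 500),
                               index=[f"p{i}" for i in range(500)])
            table, _ = simulate_survival(scores, beta=0.0, lambda0=0.1,
                                         censor_rate=0.2, seed=5000 + rep)
            rejections += cox_univariate(table, covariate="score").pval < 0.05
        assert abs(rejections / 200 - 0.05) <= 0.02

    def test_negating_covariate_negates_beta(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(0, 1, 200), index=[f"p{i}" for i in range(200)])
        table, _ = simulate_survival(scores, beta=0.7, lambda0=0.1,
                                     censor_rate=0.1, seed=4)
        r1 = cox_univariate(table, covariate="score")
        r2 = cox_univariate(table.time, covariate=-table.covariate("score"),
                            event=table.event)
        assert r2.beta == pytest.approx(-r1.beta, abs=1e-6)

    def test_ci_contains_hazard_ratio(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(0, 1, 100), index=[f"p{i}" for i in range(100)])
        table, _ = simulate_survival(scores, beta=0.4, lambda0=0.1, seed=9)
        res = cox_univariate(table, covariate="score")
        assert res.ci_low < res.hazard_ratio < res.ci_high
        assert res.hazard_ratio > 0

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(np.ones(20), covariate=np.ones(20),
                           event=np.ones(20, dtype=int))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_univariate(np.arange(1.0, 9.0), covariate=np.arange(8.0),
                           event=np.ones(8, dtype=int))


class TestScoreLogrankIdentity:
    def test_score_test_equals_logrank_without_ties(self):
        worst = 0.0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n = int(rng.integers(20, 80))
            time = rng.exponential(5.0, n)  # continuous: no ties a.s.
            event = rng.integers(0, 2, n)
            if event.sum() == 0:
                event[0] = 1
            g = rng.integers(0, 2, n)
            if g.min() == g.max():
                g[0] = 1 - g[0]
            chi2_lr, _ = logrank_test(time, event, g)
            chi2_sc, _ = cox_score_test(time, event, g.astype(float))
            worst = max(worst, abs(chi2_lr - chi2_sc))
        assert worst <= 1e-8
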