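"""Kaplan-Meier, logrank, Cox comparisons, PVE, C-index, Fisher, PH, AIC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigcombine import (
    SurvivalData,
    concordance_index,
    fisher_exact_or,
    km_estimate,
    logrank_test,
    multivariate_cox,
    ph_test,
    pve,
    stepwise_aic,
    univariate_cox,
)
from sigcombine.evaluation import analysis_of_deviance, fit_cox

from conftest import make_survival


class TestKM:
    def test_all_events_distinct_times(self):
        surv = SurvivalData(list("abcd"), [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        curve = km_estimate(surv)["all"]
        steps = curve.survival[np.isin(curve.times, [1, 2, 3, 4])]
        assert np.allclose(steps, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_stays_one(self):
        surv = SurvivalData(list("abc"), [1.0, 2.0, 3.0], [0, 0, 0])
        curve = km_estimate(surv)["all"]
        assert np.allclose(curve.survival, 1.0)

    def test_hand_computed_mixed_example(self):
        # events at 1 (n=6), 3 (n=4), 5 (n=2); censored at 2 and 4:
        # S = 5/6, then 5/6*3/4, then 5/6*3/4*1/2
        surv = SurvivalData(
            list("abcdef"), [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1, 0, 1, 0, 1, 0],
        )
        curve = km_estimate(surv)["all"]
        value_at = dict(zip(curve.times, curve.survival))
        assert value_at[1.0] == pytest.approx(5 / 6)
        assert value_at[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert value_at[5.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=40)
        surv = SurvivalData([f"s{i}" for i in range(40)], t, np.ones(40, int))
        curve = km_estimate(surv)["all"]
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((t > time).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero(self, rng):
        surv0 = make_survival(rng, 20)
        surv = SurvivalData(
            [f"s{i}" for i in range(40)],
            np.concatenate([surv0.time, surv0.time]),
            np.concatenate([surv0.event, surv0.event]),
        )
        groups = np.array(["a"] * 20 + ["b"] * 20)
        chi2, df, p = logrank_test(surv, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        surv = make_survival(rng, 50)
        groups = np.where(rng.random(50) < 0.5, "a", "b")
        chi2a, _, _ = logrank_test(surv, groups)
        swapped = np.where(groups == "a", "b", "a")
        chi2b, _, _ = logrank_test(surv, swapped)
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(50):
            n = 30
            surv = make_survival(rng, n)
            groups = np.where(rng.random(n) < 0.5, "a", "b")
            if len(np.unique(groups)) < 2:
                continue
            chi2, _, p = logrank_test(surv, groups)
            a = groups == "a"
            res = ll_logrank(
                surv.time[a], surv.time[~a], surv.event[a], surv.event[~a]
            )
            assert chi2 == pytest.approx(res.test_statistic, abs=1e-8)
            assert p == pytest.approx(res.p_value, abs=1e-8)

    def test_single_group_rejected(self, rng):
        surv = make_survival(rng, 10)
        with pytest.raises(ValueError):
            logrank_test(surv, np.array(["a"] * 10))

    def test_null_calibration(self, rng):
        # random labels: rejection rate at alpha=0.05 must sit near 0.05
        reps = 2000
        n = 100
        rejections = 0
        for _ in range(reps):
            surv = make_survival(rng, n)
            groups = np.where(rng.random(n) < 0.5, "a", "b")
            if len(np.unique(groups)) < 2:
                continue
            _, _, p = logrank_test(surv, groups)
            if p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.012)


class TestPVE:
    def test_zero_gain_gives_zero(self):
        assert pve(-100.0, -100.0, 50) == 0.0

    def test_monotone_in_gain(self):
        assert pve(-100.0, -92.0, 50) > pve(-100.0, -96.0, 50)

    def test_closed_form_value(self):
        # gain 4.3 on 77 subjects: 1 - exp(-8.6/77), the scale on which a
        # deviance near 8.6 pairs with a PVE near 0.106
        assert pve(-100.0, -95.7, 77) == pytest.approx(
            1 - math.exp(-8.6 / 77)
        )
        assert pve(-100.0, -95.7, 77) == pytest.approx(0.1057, abs=2e-4)

    def test_worse_fit_rejected(self):
        with pytest.raises(ValueError):
            pve(-100.0, -101.0, 50)


class TestConcordance:
    def test_constant_predictor_half(self, rng):
        surv = make_survival(rng, 20)
        assert concordance_index(np.zeros(20), surv) == 0.5

    def test_perfect_order_no_censoring_one(self, rng):
        n = 15
        t = np.sort(rng.exponential(10, n))
        surv = SurvivalData([f"s{i}" for i in range(n)], t, np.ones(n, int))
        # predictor = reverse event order: highest risk fails first
        pi = -np.arange(n, dtype=float)
        assert concordance_index(pi, surv) == 1.0

    def test_matches_pair_enumeration(self, rng):
        surv = SurvivalData(
            list("abcde"), [2.0, 5.0, 1.0, 8.0, 3.0], [1, 0, 1, 1, 0]
        )
        pi = np.array([0.3, -0.1, 0.9, -0.5, 0.3])
        num = den = 0.0
        n = 5
        for i in range(n):
            for j in range(n):
                if surv.time[i] < surv.time[j] and surv.event[i] == 1:
                    den += 1
                    if pi[i] > pi[j]:
                        num += 1
                    elif pi[i] == pi[j]:
                        num += 0.5
        assert concordance_index(pi, surv) == pytest.approx(num / den)

    def test_invariant_under_monotone_transform(self, rng):
        surv = make_survival(rng, 30)
        pi = rng.standard_normal(30)
        a = concordance_index(pi, surv)
        b = concordance_index(np.exp(3 * pi) + 7, surv)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_usable_pairs_rejected(self):
        surv = SurvivalData(["a", "b"], [1.0, 2.0], [0, 1])
        # only orderable pair needs the earlier time to be an event
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0, 2.0]), surv)


class TestFisher:
    def test_balanced_table(self):
        or_hat, (lo, hi), p = fisher_exact_or([[5, 5], [5, 5]])
        assert or_hat == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_diagonal_table_p(self):
        _, _, p = fisher_exact_or([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_or([[0, 0], [3, 4]])

    def test_matches_hypergeometric_enumeration(self, rng):
        # independent oracle: two-sided point-probability rule computed by
        # direct enumeration of the conditional distribution
        def enum_p(a, b, c, d):
            r1, n1 = a + b, a + c
            n = a + b + c + d
            k_lo, k_hi = max(0, r1 + n1 - n), min(r1, n1)
            ks = np.arange(k_lo, k_hi + 1)
            probs = stats.hypergeom.pmf(ks, n, n1, r1)
            p_obs = stats.hypergeom.pmf(a, n, n1, r1)
            return float(probs[probs <= p_obs * (1 + 1e-9)].sum())

        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            table = [[a, b], [c, d]]
            m = np.asarray(table)
            if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
                continue
            _, _, p = fisher_exact_or(table)
            assert p == pytest.approx(enum_p(a, b, c, d), abs=1e-8)


class TestUnivariateCox:
    def test_two_group_beta_matches_grid_search(self, rng):
        from sigcombine import partial_loglik

        n = 40
        group = (rng.random(n) < 0.5).astype(float)
        surv = make_survival(rng, n, group[:, None], np.array([0.9]))
        labels = np.where(group == 1, "high", "low")
        summary = univariate_cox(surv, labels, name="risk")
        term = summary.hr["risk:high (vs low)"]
        grid = np.linspace(-3, 3, 120001)
        values = [partial_loglik(np.array([b]), group[:, None], surv)
                  for b in grid]
        beta_oracle = grid[int(np.argmax(values))]
        assert math.log(term[0]) == pytest.approx(beta_oracle, abs=1e-4)

    def test_null_predictor_ci_covers_one(self, rng):
        # 95% Wald CI should contain HR=1 in roughly 95% of null replicates
        cover = 0
        reps = 200
        for _ in range(reps):
            n = 120
            surv = make_survival(rng, n)
            labels = np.where(rng.random(n) < 0.5, "high", "low")
            summary = univariate_cox(surv, labels)
            if not summary.converged:
                continue
            _, lo, hi, _ = summary.hr["predictor:high (vs low)"]
            if lo <= 1.0 <= hi:
                cover += 1
        assert cover / reps == pytest.approx(0.95, abs=0.04)

    def test_constant_predictor_rejected(self, rng):
        surv = make_survival(rng, 10)
        with pytest.raises(ValueError):
            univariate_cox(surv, np.array(["x"] * 10))

    def test_deviance_and_pve_rank_identically(self, rng):
        # fixed n: deviance and PVE are monotonically linked
        n = 80
        X = rng.standard_normal((n, 1))
        surv = make_survival(rng, n, X, np.array([0.8]))
        rows = []
        for noise in [0.0, 1.0, 3.0]:
            pred = X[:, 0] + noise * rng.standard_normal(n)
            s = univariate_cox(surv, pred, name="p")
            rows.append((s.deviance, s.pve))
        devs = [r[0] for r in rows]
        pves = [r[1] for r in rows]
        assert np.argsort(devs).tolist() == np.argsort(pves).tolist()

    def test_perfect_separation_flagged(self):
        # predictor exactly orders an uncensored cohort: monotone likelihood
        n = 12
        t = np.arange(1.0, n + 1)
        surv = SurvivalData([f"s{i}" for i in range(n)], t, np.ones(n, int))
        summary = univariate_cox(surv, -t, name="sep")
        assert not summary.converged
        assert math.isnan(summary.deviance)


class TestMultivariateCox:
    def test_single_stratum_equals_unstratified(self, rng):
        n = 50
        X = rng.standard_normal((n, 2))
        surv = make_survival(rng, n, X, np.array([0.5, -0.5]))
        covs = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1]},
                            index=surv.sample_ids)
        plain = multivariate_cox(surv, covs)
        strat = multivariate_cox(surv, covs, strata=np.zeros(n))
        assert np.allclose(plain.fit.beta, strat.fit.beta, atol=1e-8)

    def test_duplicated_strata_reproduce_single_copy(self, rng):
        # two strata that are exact copies of one dataset share the estimate
        n = 30
        X = rng.standard_normal((n, 2))
        surv = make_survival(rng, n, X, np.array([0.7, -0.4]))
        single = fit_cox(X, surv.time, surv.event)
        X2 = np.vstack([X, X])
        t2 = np.concatenate([surv.time, surv.time])
        e2 = np.concatenate([surv.event, surv.event])
        strata = np.array([0] * n + [1] * n)
        double = fit_cox(X2, t2, e2, strata=strata)
        assert np.allclose(double.beta, single.beta, atol=1e-6)

    def test_stratum_constant_covariate_flagged(self, rng):
        n = 40
        surv = make_survival(rng, n)
        strata = np.array([0] * 20 + [1] * 20)
        covs = pd.DataFrame({"same_as_stratum": strata.astype(float)},
                            index=surv.sample_ids)
        with pytest.raises(ValueError, match="identifiable"):
            multivariate_cox(surv, covs, strata=strata)

    def test_partial_pve_decomposition(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        surv = make_survival(rng, n, X, np.array([0.8, 0.0]))
        covs = pd.DataFrame({"signal": X[:, 0], "noise": X[:, 1]},
                            index=surv.sample_ids)
        summary = multivariate_cox(surv, covs)
        assert summary.partial_pve["signal"] > summary.partial_pve["noise"]


class TestPHTest:
    def test_matches_lifelines_km_transform(self, rng):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        for _ in range(10):
            n = 70
            X = rng.standard_normal((n, 2))
            surv = make_survival(rng, n, X, np.array([0.7, -0.4]))
            fit = fit_cox(X, surv.time, surv.event, names=["x0", "x1"])
            if not fit.converged:
                continue
            per, _ = ph_test(fit)
            frame = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1],
                                  "T": surv.time, "E": surv.event})
            cph = CoxPHFitter().fit(frame, "T", "E")
            oracle = proportional_hazard_test(cph, frame, time_transform="km")
            for name, p_oracle in zip(oracle.summary.index,
                                      oracle.summary["p"]):
                assert per[name] == pytest.approx(p_oracle, abs=0.01)

    def test_calibrated_under_ph(self, rng):
        rejections = 0
        reps = 400
        used = 0
        for _ in range(reps):
            n = 80
            X = rng.standard_normal((n, 1))
            surv = make_survival(rng, n, X, np.array([0.5]))
            fit = fit_cox(X, surv.time, surv.event)
            if not fit.converged:
                continue
            used += 1
            _, global_p = ph_test(fit)
            if global_p < 0.05:
                rejections += 1
        assert used > 0.95 * reps
        assert rejections / used == pytest.approx(0.05, abs=0.03)

    def test_detects_time_reversing_effect(self, rng):
        rejections = 0
        reps = 50
        for _ in range(reps):
            n = 120
            x = rng.standard_normal(n)
            early = rng.exponential(1 / (0.08 * np.exp(x)))
            late = 5 + rng.exponential(1 / (0.08 * np.exp(-x)))
            event_time = np.where(early < 5, early, late)
            censor = rng.uniform(0, 40, n)
            time = np.maximum(np.minimum(event_time, censor), 1e-6)
            event = (event_time <= censor).astype(int)
            fit = fit_cox(x[:, None], time, event)
            if not fit.converged:
                continue
            _, global_p = ph_test(fit)
            if global_p < 0.05:
                rejections += 1
        assert rejections >= 0.8 * reps

    def test_too_few_events_flagged(self):
        surv = SurvivalData(list("abcd"), [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        fit = fit_cox(np.arange(4.0)[:, None], surv.time, surv.event)
        with pytest.raises(ValueError):
            ph_test(fit)


class TestStepwiseAIC:
    def test_empty_model_aic(self, rng):
        from sigcombine.coxridge import partial_loglik as pll

        n = 40
        surv = make_survival(rng, n)
        cands = pd.DataFrame({"x": rng.standard_normal(n)},
                             index=surv.sample_ids)
        _, _, trace = stepwise_aic(surv, cands)
        start_aic = trace[0][2]
        l0 = pll(np.zeros(1), np.zeros((n, 1)), surv)
        assert start_aic == pytest.approx(-2 * l0)

    def test_selects_signal_rejects_noise(self, rng):
        # the strong covariate must enter essentially always; the pure-noise
        # one enters at the AIC admission rate P(chi2_1 > 2) ~ 0.157
        signal_in = 0
        noise_in = 0
        reps = 40
        for _ in range(reps):
            n = 100
            signal = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            surv = make_survival(rng, n, signal[:, None], np.array([1.0]))
            cands = pd.DataFrame({"signal": signal, "noise": noise},
                                 index=surv.sample_ids)
            selected, _, _ = stepwise_aic(surv, cands)
            if "signal" in selected:
                signal_in += 1
            if "noise" in selected:
                noise_in += 1
        assert signal_in >= 0.95 * reps
        assert noise_in <= 0.35 * reps

    def test_small_improvement_rejected_by_aic_arithmetic(self, rng):
        # adding a parameter with LR improvement < 2 raises AIC, so the
        # final model never contains such a covariate
        n = 150
        surv = make_survival(rng, n)
        pure_noise = rng.standard_normal(n)
        cands = pd.DataFrame({"noise": pure_noise}, index=surv.sample_ids)
        selected, final, trace = stepwise_aic(surv, cands)
        fit = fit_cox(pure_noise[:, None], surv.time, surv.event)
        gain = 2 * (fit.loglik - fit.loglik0)
        if gain < 2:
            assert selected == []
        else:
            assert selected == ["noise"]

    def test_analysis_of_deviance_between_nested_fits(self, rng):
        n = 80
        X = rng.standard_normal((n, 2))
        surv = make_survival(rng, n, X, np.array([0.9, 0.0]))
        small = fit_cox(X[:, :1], surv.time, surv.event)
        big = fit_cox(X, surv.time, surv.event)
        p = analysis_of_deviance(small, big)
        dev = 2 * (big.loglik - small.loglik)
        assert p == pytest.approx(stats.chi2.sf(dev, df=1))
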