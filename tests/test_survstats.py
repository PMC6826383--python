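"""Prognostic statistics against brute-force and library oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budscreen import (
    auc_mann_whitney,
    auc_with_optimism,
    backward_elimination,
    bootstrap_correct,
    cox_fit,
    logrank_chi2,
    optimal_cutpoint,
    reverse_km_median,
    roc_sample_size,
)


def brute_auc(values, labels):
    values = np.asarray(values, float)
    pos = values[np.asarray(labels) == 1]
    neg = values[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example(self):
        # pos {3,5}, neg {1,3,4}: (1 + 0.5 + 0 + 3)/6
        res = auc_mann_whitney([3, 5, 1, 3, 4], [1, 1, 0, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc_mann_whitney([5, 6, 1, 2], [1, 1, 0, 0]).auc == 1.0

    def test_all_tied_is_chance(self):
        res = auc_mann_whitney([4.0] * 6, [1, 1, 0, 0, 0, 0])
        assert res.auc == 0.5
        assert res.p_value == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2, 3], [1, 1, 1])

    def test_low_risk_orientation_not_flipped(self):
        res = auc_mann_whitney([1, 2, 8, 9], [1, 1, 0, 0])
        assert res.auc == 0.0

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_equals_brute_force_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        values = data.draw(st.lists(
            st.integers(0, 12), min_size=n, max_size=n))  # integer -> many ties
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        res = auc_mann_whitney(values, labels)
        assert res.auc == pytest.approx(brute_auc(values, labels))

    def test_negation_sums_to_one(self, rng):
        v = rng.normal(size=40)
        lab = rng.integers(0, 2, 40)
        lab[:2] = [0, 1]
        a1 = auc_mann_whitney(v, lab).auc
        a2 = auc_mann_whitney(-v, lab).auc
        assert a1 + a2 == pytest.approx(1.0)


class TestBootstrap:
    def test_constant_statistic_zero_optimism(self):
        df = pd.DataFrame(dict(x=np.arange(30.0), event=[0, 1] * 15))
        out = bootstrap_correct(lambda fit, ev: 3.25, df, B=50, seed=1)
        assert out["corrected"] == pytest.approx(3.25)
        assert out["optimism"] == 0.0

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(dict(x=rng.normal(size=60), event=rng.integers(0, 2, 60)))
        stat = lambda fit, ev: auc_mann_whitney(ev["x"], ev["event"]).auc
        a = bootstrap_correct(stat, df, B=40, seed=11)
        b = bootstrap_correct(stat, df, B=40, seed=11)
        assert a == b

    def test_null_feature_corrected_auc_near_half(self):
        """Pure-noise feature, n=102 with 20 events: corrected AUC ~ 0.5."""
        rng = np.random.default_rng(2)
        labels = np.zeros(102, int)
        labels[:20] = 1
        res = auc_with_optimism(rng.normal(size=102), labels, B=1000, seed=3)
        assert abs(res.corrected_auc - 0.5) < 0.05

    def test_vectorized_matches_generic_definition(self):
        """auc_with_optimism implements the same optimism definition as the
        generic bootstrap (identity rule makes the evaluated-on-original
        term the apparent AUC)."""
        rng = np.random.default_rng(8)
        v = rng.normal(size=80)
        lab = np.r_[np.ones(25, int), np.zeros(55, int)]
        df = pd.DataFrame(dict(x=v, event=lab))
        # the identity rule: the "model" carried from fit to eval is the raw feature
        stat = lambda fit, ev: auc_mann_whitney(ev["x"], ev["event"]).auc
        generic = bootstrap_correct(stat, df, B=800, seed=4)
        fast = auc_with_optimism(v, lab, B=800, seed=5)
        assert fast.corrected_auc == pytest.approx(generic["corrected"], abs=0.02)


class TestOptimalCutpoint:
    def test_two_block_example(self):
        values = [1, 1, 1, 9, 9, 9]
        time = [50, 60, 70, 10, 20, 30]
        event = [0, 0, 0, 1, 1, 1]
        assert optimal_cutpoint(values, time, event) == pytest.approx(5.0)

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([2, 2, 2, 2], [1, 2, 3, 4], [1, 0, 1, 0])

    def test_min_group_fraction_admissibility(self):
        values = [1, 5, 5, 5, 5, 5, 5, 5, 5, 5]
        with pytest.raises(ValueError):
            # the only split leaves 1/10 < 0.2 in the low group
            optimal_cutpoint(values, np.arange(10.0), [1, 0] * 5, min_group_fraction=0.2)

    def test_recovers_separating_cutpoint(self, rng):
        lo = rng.normal(5, 1, 40)
        hi = rng.normal(15, 1, 20)
        values = np.r_[lo, hi]
        event = np.r_[np.zeros(40, int), np.ones(20, int)]
        time = np.r_[rng.uniform(60, 100, 40), rng.uniform(5, 40, 20)]
        cut = optimal_cutpoint(values, time, event)
        assert 5 < cut < 15


class TestLogrank:
    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        time = rng.exponential(20, 60).round(1) + 1
        event = rng.integers(0, 2, 60)
        group = rng.integers(0, 2, 60)
        event[:4] = 1
        group[:2], group[2:4] = 0, 1
        ours = logrank_chi2(time, event, group)
        ref = logrank_test(time[group == 1], time[group == 0],
                           event[group == 1], event[group == 0])
        assert ours == pytest.approx(ref.test_statistic, rel=1e-6)


def breslow_loglik(beta, time, event, x):
    """Independent oracle: Breslow partial log-likelihood, direct sum."""
    ll = 0.0
    for t in np.unique(np.asarray(time)[np.asarray(event) == 1]):
        at_risk = np.asarray(time) >= t
        dead = (np.asarray(time) == t) & (np.asarray(event) == 1)
        ll += beta * np.asarray(x)[dead].sum()
        ll -= dead.sum() * math.log(np.exp(beta * np.asarray(x)[at_risk]).sum())
    return ll


class TestCox:
    def test_identical_groups_null_hr(self):
        time = [10, 20, 30, 40, 10, 20, 30, 40]
        event = [1, 0, 1, 0, 1, 0, 1, 0]
        x = pd.DataFrame(dict(g=[0, 0, 0, 0, 1, 1, 1, 1]))
        res = cox_fit(x, time, event)
        assert res.hr[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_maximized_breslow_likelihood(self):
        time = [5, 8, 12, 20, 25, 33]
        event = [1, 1, 0, 1, 0, 0]
        x = [1, 0, 1, 0, 1, 0]  # events on both covariate levels: finite MLE
        # two-stage grid on the oracle likelihood
        grid = np.arange(-5, 5, 1e-3)
        ll = [breslow_loglik(b, time, event, x) for b in grid]
        b0 = grid[int(np.argmax(ll))]
        fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-5)
        beta_star = fine[int(np.argmax([breslow_loglik(b, time, event, x) for b in fine]))]
        res = cox_fit(pd.DataFrame(dict(x=x)), time, event)
        assert res.coef[0] == pytest.approx(beta_star, abs=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame(dict(x=[1, 0, 1])), [1, 2, 3], [0, 0, 0])

    def test_hr_is_exp_coef(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(dict(z=rng.normal(size=50)))
        time = rng.exponential(30, 50) + 1
        event = rng.integers(0, 2, 50)
        event[:5] = 1
        res = cox_fit(x, time, event)
        assert res.hr[0] == pytest.approx(math.exp(res.coef[0]))


class TestBackwardElimination:
    @staticmethod
    def _cohort(seed, n=300):
        rng = np.random.default_rng(seed)
        strong = rng.normal(size=n)
        base_t = rng.exponential(50, n) / np.exp(0.8 * strong)
        cens = rng.uniform(30, 80, n)
        time = np.minimum(base_t, cens).round(2) + 0.01
        event = (base_t <= cens).astype(int)
        df = pd.DataFrame(dict(
            strong=strong,
            null1=rng.normal(size=n),
            null2=rng.normal(size=n),
            null3=rng.normal(size=n),
        ))
        return df, time, event

    def test_strong_feature_retained_across_replicates(self):
        hits = 0
        for seed in range(5):
            df, time, event = self._cohort(seed)
            kept, _ = backward_elimination(df, time, event)
            hits += "strong" in kept
        assert hits >= 4  # >= 90% retention in expectation

    def test_single_significant_candidate_kept(self):
        df, time, event = self._cohort(9)
        kept, fit = backward_elimination(df[["strong"]], time, event)
        assert kept == ["strong"]
        assert fit.p_values[0] < 0.05

    def test_pure_noise_may_be_empty(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(dict(a=rng.normal(size=80)))
        time = rng.exponential(30, 80) + 1
        event = rng.integers(0, 2, 80)
        event[:4] = 1
        kept, fit = backward_elimination(df, time, event, p_enter=1e-6)
        assert kept == [] and fit is None


class TestNullCalibration:
    """Behavior of the cutpoint + Cox machinery when there is no signal."""

    @staticmethod
    def _null_cohort(rng, n=60, k=12):
        values = rng.normal(size=n)
        event = np.zeros(n, int)
        event[:k] = 1
        time = np.where(event == 1, rng.uniform(10, 90, n), rng.uniform(70, 160, n))
        return values, time, event

    def test_selected_cutpoint_logrank_p_anticonservative(self):
        """The log-rank p at the *selected* cutpoint is biased small under
        the null (the reason reported p-values need external correction)."""
        from budscreen.survstats import logrank_chi2
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(20):
            values, time, event = self._null_cohort(rng)
            cut = optimal_cutpoint(values, time, event)
            chi2 = logrank_chi2(time, event, (values > cut).astype(int))
            pvals.append(sps.chi2.sf(chi2, 1))
        assert np.median(pvals) < 0.35  # uniform p would give ~0.5

    def test_optimism_correction_shrinks_refitted_rule_auc(self):
        """When the rule (cutpoint) is re-selected on each resample, the
        corrected AUC moves toward 0.5 relative to the apparent AUC in most
        null replicates."""

        def dichotomized_auc(fit_df, eval_df):
            cut = optimal_cutpoint(
                fit_df["x"], fit_df["time"], fit_df["event"]
            )
            return auc_mann_whitney(
                (eval_df["x"] > cut).astype(float), eval_df["event"]
            ).auc

        rng = np.random.default_rng(17)
        shrunk = 0
        n_rep = 5
        for _ in range(n_rep):
            values, time, event = self._null_cohort(rng)
            df = pd.DataFrame(dict(x=values, time=time, event=event))
            out = bootstrap_correct(dichotomized_auc, df, B=100,
                                    seed=int(rng.integers(2**31)))
            shrunk += abs(out["corrected"] - 0.5) <= abs(out["apparent"] - 0.5)
        assert shrunk >= 0.8 * n_rep


class TestReverseKM:
    def test_all_censored(self):
        assert reverse_km_median([10, 20, 30], [0, 0, 0]) == 20.0

    def test_all_events_undefined(self):
        with pytest.raises(ValueError):
            reverse_km_median([5, 6, 7], [1, 1, 1])

    def test_hand_computed_mixed_case(self):
        # censoring-as-event KM: S(10)=2/3 (event at 5 just thins risk set),
        # S(20)=0 -> first time S <= 0.5 is 20
        time = [5, 10, 15, 20]
        event = [1, 0, 1, 0]
        assert reverse_km_median(time, event) == 20.0


class TestSampleSize:
    def test_reproduces_study_calculation(self):
        assert roc_sample_size(0.05, 0.80, 0.72, 4) == (17, 85)

    def test_stronger_effect_needs_fewer_cases(self):
        n_pos, _ = roc_sample_size(0.05, 0.80, 0.90, 4)
        assert n_pos < 17

    @pytest.mark.parametrize("bad_auc", [0.5, 0.4, 1.0])
    def test_unattainable_effect_rejected(self, bad_auc):
        with pytest.raises(ValueError):
            roc_sample_size(0.05, 0.8, bad_auc, 4)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            roc_sample_size(0.05, 0.8, 0.72, 0.5)
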