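import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from lifeclust import (DivergenceSpec, anova_f, brier_score, chisq_test,
                       concordance_index, km_estimate, kuiper_pvalue_ub,
                       kuiper_statistic, logrank_statistic, mmd_divergence)
from lifeclust.survival import kuiper_series_pvalue

from conftest import random_survival


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        assert np.allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_reduces_later_risk_sets(self):
        c = km_estimate([1, 2, 3], [1, 0, 1])
        assert c.event_times.tolist() == [1.0, 3.0]
        assert np.allclose(c.survival, [2 / 3, 0.0])

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(1)
        t, e = random_survival(rng, 40)
        a = km_estimate(t, e, np.ones_like(t))
        b = km_estimate(t, e, 2.0 * np.ones_like(t))
        assert np.allclose(a.survival, b.survival)

    def test_one_hot_weights_equal_classical_subset_km(self):
        rng = np.random.default_rng(2)
        t, e = random_survival(rng, 60)
        labels = rng.integers(0, 3, 60)
        for k in range(3):
            soft = km_estimate(t, e, (labels == k).astype(float))
            hard = km_estimate(t[labels == k], e[labels == k])
            assert np.array_equal(soft.event_times, hard.event_times)
            assert np.allclose(soft.survival, hard.survival)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(100, 80))
        c = km_estimate(t, np.ones_like(t))
        for u in c.event_times:
            assert np.isclose(c.survival_at(u), (t > u).mean())

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(4)
        t, e = random_survival(rng, 100)
        kmf = KaplanMeierFitter().fit(t, e)
        mine = km_estimate(t, e)
        theirs = kmf.survival_function_at_times(mine.event_times).to_numpy()
        assert np.allclose(mine.survival, theirs)

    def test_no_events_degenerate_curve(self):
        c = km_estimate([1, 2], [0, 0])
        assert c.degenerate and c.event_times.size == 0


class TestKuiper:
    def test_identical_curves_zero(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        assert kuiper_statistic(c, c) == 0.0

    def test_step_separation_one(self):
        s1 = km_estimate([1.0], [1])  # drops to 0 at t=1
        s2 = km_estimate([2.0], [1])  # stays at 1 until t=2
        v = kuiper_statistic(s1, s2)
        assert np.isclose(v, 1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        t1, e1 = random_survival(rng, 30)
        t2, e2 = random_survival(rng, 30)
        a, b = km_estimate(t1, e1), km_estimate(t2, e2)
        assert np.isclose(kuiper_statistic(a, b), kuiper_statistic(b, a))

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t1, e1 = random_survival(rng, 25)
            t2, e2 = random_survival(rng, 25)
            a, b = km_estimate(t1, e1), km_estimate(t2, e2)
            grid = np.linspace(0, 400, 200001)
            diff = a.survival_at(grid) - b.survival_at(grid)
            oracle = max(diff.max(), 0) + max((-diff).max(), 0)
            assert abs(kuiper_statistic(a, b) - oracle) < 1e-9


class TestKuiperPValueBound:
    def test_no_separation_gives_one(self):
        assert kuiper_pvalue_ub(0.0, 50, 50) == 1.0

    def test_large_separation_tiny_p(self):
        p = kuiper_pvalue_ub(1.0, 50, 50)
        assert p < 1e-20
        # cross-check against the full asymptotic series
        assert np.isclose(p, kuiper_series_pvalue(1.0, 25.0), rtol=1e-6)

    def test_monotone_non_increasing_in_v(self):
        grid = np.linspace(0.2, 2.0, 200)
        ps = [kuiper_pvalue_ub(v, 50, 50) for v in grid]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kuiper_pvalue_ub(2.5, 10, 10)
        with pytest.raises(ValueError):
            kuiper_pvalue_ub(0.5, 0, 10)


class TestMMD:
    def test_identical_weights_zero(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(100, 30)
        w = rng.random(30)
        assert np.isclose(mmd_divergence(t, w, w, 50.0), 0.0)

    def test_point_mass_hand_value(self):
        val = mmd_divergence([0.0, 1.0], [1, 0], [0, 1], 1.0)
        assert np.isclose(val, 2.0 - 2.0 * np.exp(-0.5))

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(100, 40)
        a, b = rng.random(40), rng.random(40)
        ab = mmd_divergence(t, a, b)
        assert ab >= 0
        assert np.isclose(ab, mmd_divergence(t, b, a))

    def test_zero_sum_weights_error_names_cluster(self):
        with pytest.raises(ValueError, match="cluster j"):
            mmd_divergence([1.0, 2.0], [1, 1], [0, 0], 1.0)


class TestLogrank:
    def test_identical_groups_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        assert np.isclose(logrank_statistic(t, e, g), 0.0)

    def test_two_group_hand_value(self):
        # events at 1,2 (group A) vs 3,4 (group B): U=7/6, Var=17/36
        stat = logrank_statistic([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert np.isclose(stat, (7 / 6) ** 2 / (17 / 36))

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        t, e = random_survival(rng, 60)
        g = rng.integers(0, 3, 60)
        a = logrank_statistic(t, e, g)
        b = logrank_statistic(t, e, (g + 1) % 3)
        assert np.isclose(a, b)

    def test_single_group_error(self):
        with pytest.raises(ValueError):
            logrank_statistic([1, 2], [1, 1], [0, 0])


class TestConcordance:
    def test_perfect_ordering(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0

    def test_all_ties_half(self):
        assert concordance_index([1, 2, 3], [1, 1, 1], [1, 1, 1]) == 0.5

    def test_censored_example(self):
        # pairs: (1,2) discordant, (1,3) concordant, (2,3) concordant
        assert np.isclose(concordance_index([1, 2, 3], [1, 1, 0], [2, 3, 1]),
                          2 / 3)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 1], [0, 0], [1, 2])


class TestBrier:
    def test_perfect_predictions_zero(self):
        t = np.array([100.0, 200.0, 400.0, 500.0])
        e = np.array([1, 1, 0, 0])
        pred = np.array([0.0, 0.0, 1.0, 1.0])
        assert brier_score(t, e, pred, 365.0) == 0.0

    def test_constant_half_quarter(self):
        t = np.array([100.0, 400.0])
        e = np.array([1, 1])
        assert np.isclose(brier_score(t, e, [0.5, 0.5], 365.0), 0.25)

    def test_no_censoring_reduces_to_mse(self):
        rng = np.random.default_rng(10)
        t = np.ceil(rng.exponential(300, 50))
        e = np.ones(50, dtype=int)
        pred = rng.random(50)
        mse = np.mean(((t > 200).astype(float) - pred) ** 2)
        assert np.isclose(brier_score(t, e, pred, 200.0), mse)

    def test_matches_scikit_survival_ipcw(self):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        rng = np.random.default_rng(11)
        t = rng.exponential(200.0, 120)  # continuous: no event/censor ties
        e = (rng.random(120) >= 0.4).astype(int)
        pred = rng.random(120)
        y = Surv.from_arrays(e.astype(bool), t)
        _, theirs = sks_brier(y, y, pred, [200.0])
        assert np.isclose(brier_score(t, e, pred, 200.0), theirs[0],
                          rtol=1e-8)

    def test_no_information_at_horizon_error(self):
        t = np.array([10.0, 20.0])
        e = np.array([0, 0])
        with pytest.raises(ValueError, match="horizon"):
            brier_score(t, e, [0.5, 0.5], 365.0)


class TestClassicalTests:
    def test_chisq_independence_zero(self):
        chi2, p = chisq_test([[10, 10], [10, 10]])
        assert chi2 == 0.0 and np.isclose(p, 1.0)

    def test_chisq_diagonal_forty(self):
        chi2, _ = chisq_test([[20, 0], [0, 20]])
        assert np.isclose(chi2, 40.0)

    def test_chisq_row_permutation_invariance(self):
        a, _ = chisq_test([[5, 10], [8, 3], [2, 9]])
        b, _ = chisq_test([[2, 9], [5, 10], [8, 3]])
        assert np.isclose(a, b)

    def test_chisq_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_test([[0, 0], [5, 5]])

    def test_anova_hand_value(self):
        f, _ = anova_f([[1, 2, 3], [4, 5, 6]])
        assert np.isclose(f, 13.5)

    def test_anova_identical_groups_zero(self):
        f, p = anova_f([[2, 2, 2], [2, 2, 2]])
        assert f == 0.0

    def test_anova_scale_invariance(self):
        a, _ = anova_f([[1, 2, 3], [4, 5, 6]])
        b, _ = anova_f([[10, 20, 30], [40, 50, 60]])
        assert np.isclose(a, b)
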