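import numpy as np
import pytest

from lifeclust import (AttributionResult, importance_summary,
                       shapley_attribution)


class LinearSoftmaxModel:
    """Tiny stand-in model: softmax over linear logits."""

    def __init__(self, w):
        self.w = np.asarray(w, float)  # d x K

    def predict_soft(self, x):
        z = np.asarray(x, float) @ self.w
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class AdditiveProbabilityModel:
    """Membership probabilities that are exactly additive in features."""

    def __init__(self, w, base=0.5):
        self.w = np.asarray(w, float)  # d
        self.base = base

    def predict_soft(self, x):
        p = self.base + np.asarray(x, float) @ self.w
        return np.column_stack([p, 1.0 - p])


@pytest.fixture(scope="module")
def small_problem():
    rng = np.random.default_rng(0)
    rows = rng.random((3, 6))
    background = rng.random((25, 6))
    return rows, background


class TestShapleyAttribution:
    def test_ignored_feature_gets_zero(self, small_problem):
        rows, background = small_problem
        w = np.random.default_rng(1).normal(size=(6, 3))
        w[4, :] = 0.0  # model is blind to feature 4
        attr = shapley_attribution(LinearSoftmaxModel(w), rows, background,
                                   n_permutations=30, seed=0)
        assert np.allclose(attr.values[:, 4, :], 0.0)

    def test_additive_model_recovers_linear_terms(self, small_problem):
        rows, background = small_problem
        w = np.array([0.05, -0.04, 0.03, 0.02, -0.01, 0.04])
        model = AdditiveProbabilityModel(w)
        attr = shapley_attribution(model, rows, background,
                                   n_permutations=200, seed=1)
        expected = (rows - background.mean(axis=0)) * w  # n x d
        assert np.allclose(attr.values[:, :, 0], expected, atol=1e-10)

    def test_efficiency(self, small_problem):
        rows, background = small_problem
        w = np.random.default_rng(2).normal(size=(6, 3))
        model = LinearSoftmaxModel(w)
        attr = shapley_attribution(model, rows, background,
                                   n_permutations=500, seed=2)
        totals = attr.values.sum(axis=1)  # n x K
        expected = model.predict_soft(rows) - attr.baseline
        assert np.abs(totals - expected).max() < 0.02

    def test_symmetric_features_get_equal_attribution(self):
        rng = np.random.default_rng(3)
        base = rng.random((40, 1))
        rows = np.hstack([base[:2], base[:2], rng.random((2, 2))])
        background = np.hstack([base, base, rng.random((40, 2))])
        w = np.array([[0.5, -0.5], [0.5, -0.5], [0.2, 0.1], [-0.1, 0.3]])
        attr = shapley_attribution(LinearSoftmaxModel(w), rows, background,
                                   n_permutations=400, seed=3)
        assert np.abs(attr.values[:, 0, :] - attr.values[:, 1, :]).max() \
            < 0.02

    def test_monte_carlo_error_shrinks_with_permutations(self):
        rng = np.random.default_rng(4)
        rows = rng.random((1, 6))
        background = rng.random((20, 6))
        w = rng.normal(size=(6, 2))
        model = LinearSoftmaxModel(w)

        def spread(n_perm):
            reps = [shapley_attribution(model, rows, background,
                                        n_permutations=n_perm,
                                        seed=s).values[0, 0, 0]
                    for s in range(20)]
            return np.std(reps)

        ratio = spread(25) / spread(100)
        assert 1.4 < ratio < 2.9  # expect about 2 = sqrt(100/25)

    def test_empty_background_rejected(self, small_problem):
        rows, _ = small_problem
        with pytest.raises(ValueError, match="background"):
            shapley_attribution(LinearSoftmaxModel(np.zeros((6, 2))), rows,
                                np.empty((0, 6)), n_permutations=5)


class TestImportanceSummary:
    def test_zero_attributions_rank_zero(self):
        attr = AttributionResult(np.zeros((4, 3, 2)), np.zeros(2),
                                 ("a", "b", "c"))
        table = importance_summary(attr)
        assert (table["mean_abs_attribution"] == 0).all()

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(6, 4, 2))
        a = importance_summary(
            AttributionResult(vals, np.zeros(2), tuple("wxyz")))
        b = importance_summary(
            AttributionResult(vals[::-1].copy(), np.zeros(2), tuple("wxyz")))
        pa = a.pivot(index="feature", columns="cluster",
                     values="mean_abs_attribution")
        pb = b.pivot(index="feature", columns="cluster",
                     values="mean_abs_attribution")
        assert np.allclose(pa.to_numpy(), pb.to_numpy())

    def test_onehot_aggregation_sums_indicator_columns(self):
        vals = np.ones((2, 4, 2))
        attr = AttributionResult(vals, np.zeros(2),
                                 ("x", "c=A", "c=B", "c=C"))
        agg = attr.aggregate_onehot()
        assert agg.feature_names == ("x", "c")
        assert np.allclose(agg.values[:, 1, :], 3.0)

    def test_ranking_agrees_with_linear_model_influence(self):
        """For a fitted linear-softmax clustering model the Shapley
        ranking of the high-risk cluster should agree with the model's
        own weight-based feature influence (|weight contrast| x feature
        spread) — an independent route to the same ground truth."""
        from lifeclust import (HyperparameterGrid, default_stroke_spec,
                               dlc_fit, simulate_cohort, stratified_split,
                               impute, fit_transform, apply_transform)

        spec = default_stroke_spec(n=1500, seed=21, effect_scale=2.0)
        cohort = simulate_cohort(spec)
        split = stratified_split(cohort, seed=0)
        train = impute(split.train)
        val = impute(split.validation)
        fm = fit_transform(train)
        fmv = apply_transform(fm.state, val)
        grid = HyperparameterGrid(n_layers=(0,), hidden_width=(8,),
                                  learning_rate=(1e-2,),
                                  activation=("tanh",), epochs=150,
                                  n_restarts=2)
        model = dlc_fit(fm.values, train.times, train.events, fmv.values,
                        val.times, val.events, grid=grid, seed=0)
        assert model.widths == []  # linear: weight-influence is well defined
        rng = np.random.default_rng(0)
        rows = fm.values[rng.choice(fm.n, 20, replace=False)]
        bg = fm.values[rng.choice(fm.n, 60, replace=False)]
        attr = shapley_attribution(model, type(fm)(rows, fm.feature_names,
                                                   fm.state), bg,
                                   n_permutations=80, seed=0)
        table = importance_summary(attr)
        high_raw = int(model.risk_order.argmin())
        w = model.weights[0]  # d x K
        contrast = np.abs(w[:, high_raw] - w.mean(axis=1))
        influence = contrast * fm.values.std(axis=0)
        expected_top = set(np.argsort(-influence)[:8])
        got_top = [fm.feature_names.index(f) for f in
                   table[table.cluster == high_raw].nsmallest(
                       3, "rank")["feature"]]
        assert len(set(got_top) & expected_top) >= 2
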