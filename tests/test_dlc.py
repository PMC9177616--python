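import numpy as np
import pytest

from lifeclust import (DivergenceSpec, HyperparameterGrid, dlc_fit,
                       dlc_loss, dlc_loss_grad, dlc_predict,
                       logrank_statistic, order_clusters_by_risk)
from lifeclust.dlc import SoftAssignment
from lifeclust.survival import KUIPER_P_FLOOR

from conftest import random_survival

SMALL_GRID = HyperparameterGrid(n_layers=(0,), hidden_width=(8,),
                                learning_rate=(1e-2,), activation=("tanh",),
                                epochs=120)


def one_hot(labels, k):
    q = np.full((len(labels), k), 1e-9)
    q[np.arange(len(labels)), labels] = 1.0
    return q / q.sum(axis=1, keepdims=True)


class TestSoftAssignment:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SoftAssignment(np.array([[0.7, 0.6], [0.5, 0.5]]),
                           np.array([0, 0]))


class TestDLCLoss:
    def test_uniform_assignment_gives_zero_loss(self):
        rng = np.random.default_rng(0)
        t, e = random_survival(rng, 60)
        q = np.full((60, 3), 1 / 3)
        assert dlc_loss(q, t, e) == 0.0

    def test_disjoint_supports_reach_the_clamp_bound(self):
        # population A has all its events long before B starts failing;
        # effective sizes are large enough to push p below its floor
        t = np.concatenate([np.arange(1, 101), np.arange(200, 300)])
        e = np.ones(200, dtype=int)
        q = one_hot(np.repeat([0, 1], 100), 2)
        expected_delta = -np.log(KUIPER_P_FLOOR) + np.log(4 * np.exp(-1.5))
        assert np.isclose(dlc_loss(q, t, e), -expected_delta)

    def test_cluster_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t, e = random_survival(rng, 50)
        logits = rng.normal(size=(50, 3))
        q = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        assert np.isclose(dlc_loss(q, t, e), dlc_loss(q[:, [2, 0, 1]], t, e))

    def test_zero_event_mass_cluster_is_not_an_error(self):
        t = np.array([5.0, 10.0, 15.0, 20.0])
        e = np.array([1, 1, 0, 0])
        # cluster 2 holds only censored rows -> its pairwise deltas are 0
        q = one_hot(np.array([0, 1, 2, 2]), 3)
        loss = dlc_loss(q, t, e)
        assert np.isfinite(loss)

    def test_mmd_variant_uses_kernel_divergence(self):
        rng = np.random.default_rng(2)
        t, e = random_survival(rng, 40)
        q = one_hot(rng.integers(0, 2, 40), 2)
        div = DivergenceSpec(kind="mmd", mmd_bandwidth=60.0)
        assert np.isfinite(dlc_loss(q, t, e, div))

    def test_gradient_matches_finite_differences(self):
        # spot check here; the exhaustive sweep lives in the acceptance suite
        rng = np.random.default_rng(3)
        t, e = random_survival(rng, 40)
        logits = rng.normal(size=(40, 3))
        q = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        val, grad = dlc_loss_grad(q, t, e)
        h = 1e-6
        for i, k in [(0, 0), (7, 2), (21, 1)]:
            qp, qm = q.copy(), q.copy()
            qp[i, k] += h
            qm[i, k] -= h
            fd = (dlc_loss(qp, t, e) - dlc_loss(qm, t, e)) / (2 * h)
            assert np.isclose(grad[i, k], fd, rtol=1e-4, atol=1e-8)


class TestRiskOrdering:
    def test_sorts_by_one_year_event_probability(self):
        # per-cluster rates 0.06 / 0.45 / 0.13 by raw label
        rng = np.random.default_rng(4)
        times, labels = [], []
        for raw, p in enumerate([0.06, 0.45, 0.13]):
            lam = -np.log1p(-p) / 365.0
            t = np.ceil(rng.exponential(1 / lam, 400)).clip(1, None)
            times.append(np.minimum(t, 365.0))
            labels.append(np.full(400, raw))
        times = np.concatenate(times)
        labels = np.concatenate(labels)
        events = (times < 365).astype(int)
        perm = order_clusters_by_risk(labels, times, events)
        assert perm.tolist() == [2, 0, 1]

    def test_already_ordered_is_identity(self):
        t = np.array([10.0, 20.0, 300.0, 350.0, 360.0, 365.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        lab = np.array([0, 0, 1, 1, 2, 2])
        assert order_clusters_by_risk(lab, t, e).tolist() == [0, 1, 2]

    def test_ties_broken_by_size(self):
        t = np.full(9, 365.0)
        e = np.zeros(9, dtype=int)
        t[:3] = [10, 10, 10]
        e[:3] = 1  # cluster 0: 3 events of 3 rows
        lab = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2])
        # clusters 1 and 2 both have zero events; larger cluster 1 first
        perm = order_clusters_by_risk(lab, t, e)
        assert perm.tolist() == [0, 1, 2]


@pytest.fixture(scope="module")
def fitted_model(prepared_split):
    train, fm = prepared_split["train"]
    val, fmv = prepared_split["validation"]
    return dlc_fit(fm.values, train.times, train.events, fmv.values,
                   val.times, val.events, grid=SMALL_GRID, seed=0), fm


class TestDLCFit:
    def test_determinism(self, prepared_split):
        train, fm = prepared_split["train"]
        val, fmv = prepared_split["validation"]
        kwargs = dict(grid=SMALL_GRID, seed=7)
        a = dlc_fit(fm.values, train.times, train.events, fmv.values,
                    val.times, val.events, **kwargs)
        b = dlc_fit(fm.values, train.times, train.events, fmv.values,
                    val.times, val.events, **kwargs)
        assert a.selected_config == b.selected_config
        assert a.risk_order.tolist() == b.risk_order.tolist()
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.weights, b.weights))

    def test_predictions_are_row_stochastic(self, fitted_model):
        model, fm = fitted_model
        assign = dlc_predict(model, fm.values)
        assert np.allclose(assign.q.sum(axis=1), 1.0)

    def test_duplicated_row_identical_assignment(self, fitted_model):
        model, fm = fitted_model
        x = np.vstack([fm.values[0], fm.values[0]])
        q = model.predict_soft(x)
        assert np.array_equal(q[0], q[1])

    def test_feature_dimension_mismatch_error(self, fitted_model):
        model, fm = fitted_model
        with pytest.raises(ValueError, match="dimension"):
            model.predict_soft(fm.values[:, :5])

    def test_risk_order_consistent_with_training_labels(self, fitted_model,
                                                        prepared_split):
        model, fm = fitted_model
        train, _ = prepared_split["train"]
        raw = model.predict_soft(fm.values).argmax(axis=1)
        recomputed = order_clusters_by_risk(raw, train.times, train.events,
                                            n_clusters=model.n_clusters)
        assert np.array_equal(recomputed, model.risk_order)

    def test_too_small_training_split_rejected(self):
        x = np.random.default_rng(0).random((30, 4))
        with pytest.raises(ValueError, match="too small"):
            dlc_fit(x, np.arange(1, 31), np.ones(30, int), x,
                    np.arange(1, 31), np.ones(30, int), grid=SMALL_GRID)

    def test_save_load_round_trip(self, fitted_model, tmp_path):
        model, fm = fitted_model
        path = tmp_path / "model.json"
        model.save(path)
        from lifeclust import DLCModel
        back = DLCModel.load(path)
        assert np.allclose(back.predict_soft(fm.values[:10]),
                           model.predict_soft(fm.values[:10]))

    def test_noise_covariates_find_no_test_separation(self, prepared_split):
        """On pure-noise features the fitted clusters should carry no
        survival signal on held-out data (permutation-null check)."""
        train, fm = prepared_split["train"]
        val, _ = prepared_split["validation"]
        test, _ = prepared_split["test"]
        rng = np.random.default_rng(5)
        xt = rng.random((len(train), 10))
        xv = rng.random((len(val), 10))
        xs = rng.random((len(test), 10))
        model = dlc_fit(xt, train.times, train.events, xv, val.times,
                        val.events, grid=SMALL_GRID, seed=1)
        labels = model.predict(xs).hard_labels
        if np.unique(labels).size < 2:
            return  # collapsed to one cluster on test: trivially no signal
        observed = logrank_statistic(test.times, test.events, labels)
        null = []
        for _ in range(200):
            null.append(logrank_statistic(test.times, test.events,
                                          rng.permutation(labels)))
        assert observed <= np.quantile(null, 0.995)
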