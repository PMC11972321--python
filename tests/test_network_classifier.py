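"""Dense network forward/loss contracts, PCSO training, and explanations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiopcso import network as net
from cardiopcso.classifier import (
    FittedClassifier,
    explain,
    fitness_from_weights,
    load_fitted,
    local_sensitivity,
    save_fitted,
    train_with_pcso,
)
from cardiopcso.pcso import PCSOConfig
from cardiopcso.synthetic import gen_separable


@pytest.fixture(scope="module")
def tiny_spec():
    return net.NetworkSpec(input_dim=4, hidden=(8, 4), batch_norm=True)


def random_weights(spec, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-1, 1, net.n_params(spec))


class TestLayoutAndForward:
    def test_flatten_roundtrip_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            spec = net.NetworkSpec(
                input_dim=int(rng.integers(1, 10)),
                hidden=tuple(int(rng.integers(1, 16)) for _ in range(int(rng.integers(1, 4)))),
                batch_norm=bool(rng.integers(0, 2)),
            )
            v = rng.normal(size=net.n_params(spec))
            assert np.array_equal(net.flatten(spec, net.unflatten(spec, v)), v)

    def test_zero_weights_give_half(self, tiny_spec):
        X = np.random.default_rng(0).normal(size=(10, 4))
        probs = net.forward(tiny_spec, np.zeros(net.n_params(tiny_spec)), X)
        np.testing.assert_allclose(probs, 0.5)

    def test_duplicated_row_identical_output(self, tiny_spec):
        w = random_weights(tiny_spec)
        X = np.random.default_rng(1).normal(size=(6, 4))
        X2 = np.vstack([X, X[:1]])
        bn = net.compute_bn_stats(tiny_spec, w, X)
        p = net.forward(tiny_spec, w, X2, bn)
        assert p[0] == p[-1]

    def test_outputs_strictly_in_unit_interval(self, tiny_spec):
        w = random_weights(tiny_spec, 2)
        X = np.random.default_rng(2).normal(size=(50, 4)) * 10
        p = net.forward(tiny_spec, w, X)
        assert ((p > 0) & (p < 1)).all()

    def test_shape_mismatch(self, tiny_spec):
        with pytest.raises(ValueError):
            net.forward(tiny_spec, random_weights(tiny_spec), np.zeros((3, 5)))
        with pytest.raises(ValueError):
            net.unflatten(tiny_spec, np.zeros(3))

    def test_inference_pure_function(self, tiny_spec):
        w = random_weights(tiny_spec, 3)
        X = np.random.default_rng(3).normal(size=(20, 4))
        bn = net.compute_bn_stats(tiny_spec, w, X)
        a = net.forward(tiny_spec, w, X, bn)
        b = net.forward(tiny_spec, w, X, bn)
        np.testing.assert_array_equal(a, b)


class TestWeightedBce:
    def test_perfect_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        p = np.array([1 - 1e-7, 1e-7, 1 - 1e-7])
        assert net.weighted_bce(p, y) < 1e-5

    def test_coin_flip_is_log2(self):
        y = np.array([0.0, 1.0] * 10)
        p = np.full(20, 0.5)
        assert net.weighted_bce(p, y) == pytest.approx(np.log(2), abs=1e-12)

    def test_class_weight_scales_positive_term_only(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 40).astype(float)
        p = rng.uniform(0.1, 0.9, 40)
        l1 = net.weighted_bce(p, y, class_weight=1.0)
        l2 = net.weighted_bce(p, y, class_weight=2.0)
        pos_term = -(y * np.log(p)).mean()
        assert l2 - l1 == pytest.approx(pos_term, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            net.weighted_bce(np.zeros(3), np.zeros(4))


class TestFitness:
    def test_better_weights_smaller_fitness(self, tiny_spec):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        split = ((X[:40], y[:40]), (X[40:], y[40:]))
        w_bad = np.zeros(net.n_params(tiny_spec))
        # a weight vector that predicts from the informative feature
        best = None
        for s in range(30):
            w = random_weights(tiny_spec, s)
            f = fitness_from_weights(w, tiny_spec, *split)
            if best is None or f < best[0]:
                best = (f, w)
        f_bad = fitness_from_weights(w_bad, tiny_spec, *split)
        assert best[0] < f_bad  # some random net beats the all-zero coin flip

    def test_finite_for_random_weights(self, tiny_spec):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        f = fitness_from_weights(
            random_weights(tiny_spec, 1) * 3, tiny_spec, (X[:20], y[:20]), (X[20:], y[20:])
        )
        assert np.isfinite(f)

    def test_empty_validation_raises(self, tiny_spec):
        X = np.zeros((4, 4))
        y = np.zeros(4)
        with pytest.raises(ValueError):
            fitness_from_weights(random_weights(tiny_spec), tiny_spec, (X, y), (X[:0], y[:0]))


class TestTrainWithPcso:
    def test_separable_data_high_accuracy_small_net(self):
        # small architecture keeps this a fast smoke check; the full
        # 128/64/32 calibration lives in the acceptance suite
        X, y = gen_separable(n=300, seed=0)
        Xz = (X - X.mean(0)) / X.std(0)
        spec = net.NetworkSpec(input_dim=2, hidden=(16, 8))
        cfg = PCSOConfig(
            dim=net.n_params(spec), lower=-3, upper=3, pop_size=20, max_iters=60, seed=0
        )
        model, res = train_with_pcso(spec, Xz[:240], y[:240], pcso_config=cfg, seed=0)
        assert (model.predict(Xz[240:]) == y[240:]).mean() >= 0.9
        assert np.all(np.diff(res.history) <= 0)

    def test_end_to_end_determinism(self):
        X, y = gen_separable(n=120, seed=1)
        spec = net.NetworkSpec(input_dim=2, hidden=(8,))
        cfg = PCSOConfig(dim=net.n_params(spec), lower=-2, upper=2, pop_size=10, max_iters=20, seed=3)
        m1, r1 = train_with_pcso(spec, X, y, pcso_config=cfg, seed=3)
        cfg2 = PCSOConfig(dim=net.n_params(spec), lower=-2, upper=2, pop_size=10, max_iters=20, seed=3)
        m2, r2 = train_with_pcso(spec, X, y, pcso_config=cfg2, seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(r1.history, r2.history)

    def test_dim_mismatch_rejected(self):
        spec = net.NetworkSpec(input_dim=2, hidden=(4,))
        with pytest.raises(ValueError):
            train_with_pcso(
                spec, np.zeros((20, 2)), np.r_[np.zeros(10), np.ones(10)],
                pcso_config=PCSOConfig(dim=3, lower=-1, upper=1, pop_size=4, max_iters=5),
            )

    def test_refine_improves_or_matches_train_loss(self):
        X, y = gen_separable(n=200, seed=2)
        Xz = (X - X.mean(0)) / X.std(0)
        spec = net.NetworkSpec(input_dim=2, hidden=(8, 4))
        cfg = PCSOConfig(dim=net.n_params(spec), lower=-2, upper=2, pop_size=8, max_iters=10, seed=0)
        raw, _ = train_with_pcso(spec, Xz, y, pcso_config=cfg, seed=0)
        cfg2 = PCSOConfig(dim=net.n_params(spec), lower=-2, upper=2, pop_size=8, max_iters=10, seed=0)
        ref, _ = train_with_pcso(spec, Xz, y, pcso_config=cfg2, seed=0, refine=True, refine_epochs=30)
        loss_raw = net.weighted_bce(raw.predict_proba(Xz), y)
        loss_ref = net.weighted_bce(ref.predict_proba(Xz), y)
        assert loss_ref <= loss_raw + 0.05


@pytest.fixture(scope="module")
def fitted_on_one_signal():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(400, 5))
    y = (X[:, 2] + 0.3 * rng.standard_normal(400) > 0).astype(int)
    spec = net.NetworkSpec(input_dim=5, hidden=(16, 8))
    cfg = PCSOConfig(dim=net.n_params(spec), lower=-2, upper=2, pop_size=20, max_iters=80, seed=0)
    model, _ = train_with_pcso(spec, X[:300], y[:300], pcso_config=cfg, seed=0)
    return model, X[300:], y[300:]


class TestExplain:
    def test_planted_feature_ranks_first(self, fitted_on_one_signal):
        model, X, y = fitted_on_one_signal
        rep = explain(model, X, y, n_repeats=10, seed=0)
        assert rep.global_rank[0] == "x2"

    def test_noise_importance_near_zero(self, fitted_on_one_signal):
        model, X, y = fitted_on_one_signal
        rep = explain(model, X, y, n_repeats=10, seed=1)
        noise = [0, 1, 3, 4]
        z = rep.importance_mean[noise] / np.maximum(rep.importance_sd[noise], 1e-12)
        assert np.abs(z).max() < 3 * 2  # loose: permutation noise, fixed seed

    def test_dead_input_zero_sensitivity(self):
        spec = net.NetworkSpec(input_dim=3, hidden=(4,), batch_norm=False)
        params = net.unflatten(spec, random_weights(spec, 7))
        params["W0"][0, :] = 0.0  # feature 0 disconnected
        model = FittedClassifier(spec, net.flatten(spec, params), None)
        sens = local_sensitivity(model, np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_allclose(sens[:, 0], 0.0, atol=1e-12)

    def test_n_repeats_validation(self, fitted_on_one_signal):
        model, X, y = fitted_on_one_signal
        with pytest.raises(ValueError):
            explain(model, X, y, n_repeats=1)


def test_save_load_round_trip(tmp_path):
    spec = net.NetworkSpec(input_dim=3, hidden=(6, 4))
    w = np.random.default_rng(0).uniform(-1, 1, net.n_params(spec))
    X = np.random.default_rng(1).normal(size=(20, 3))
    bn = net.compute_bn_stats(spec, w, X)
    model = FittedClassifier(spec, w, bn)
    save_fitted(model, tmp_path / "model")
    back = load_fitted(tmp_path / "model")
    np.testing.assert_array_equal(back.weights, model.weights)
    np.testing.assert_allclose(back.predict_proba(X), model.predict_proba(X), atol=1e-12)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 1000))
def test_auc_monotone_in_effect_size(seed):
    """Not a full dose-response: just checks the planted logistic model is
    learnable in the right direction by a linear readout of probabilities."""
    from cardiopcso.synthetic import gen_tabular
    from cardiopcso.metrics import auc, roc_curve

    aucs = []
    for effect in (0.0, 1.0, 3.0):
        ds = gen_tabular(n=400, seed=seed, informative_names=["LVEF"], effect_sizes=[effect])
        j = ds.feature_names.index("LVEF")
        fpr, tpr = roc_curve(ds.y, ds.X[:, j])
        aucs.append(max(auc(fpr, tpr), 1 - auc(fpr, tpr)))
    assert aucs[2] > aucs[0] - 0.05
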