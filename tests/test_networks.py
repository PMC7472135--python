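"""Classifier correctness: loss, analytic heads vs least-squares oracles,
k selection, label recovery, determinism and serialisation."""

import numpy as np
import pytest
from scipy.special import expit

from pearnose import (
    BPELMClassifier,
    BPNNClassifier,
    ELMClassifier,
    RBFNetClassifier,
    TrainConfig,
    bpelm_train,
    bpnn_train,
    cross_entropy_l2_loss,
    elm_fit,
    load_model,
    net_predict,
    rbf_fit,
    rbf_select_k,
    save_model,
)
from pearnose.errors import ClusteringError, ConvergenceError


def onehot(y, k=6):
    T = np.zeros((len(y), k))
    T[np.arange(len(y)), y] = 1
    return T


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        T = onehot([0, 3, 5])
        assert cross_entropy_l2_loss(T, T, alpha_r=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log6(self):
        probs = np.full((4, 6), 1 / 6)
        loss = cross_entropy_l2_loss(probs, onehot([0, 1, 2, 3]))
        assert loss == pytest.approx(np.log(6), rel=1e-12)

    def test_zero_weights_vanishing_penalty(self):
        probs = np.full((2, 6), 1 / 6)
        T = onehot([0, 5])
        with_pen = cross_entropy_l2_loss(probs, T, weights=[np.zeros((3, 3))],
                                         alpha_r=1.0)
        assert with_pen == pytest.approx(cross_entropy_l2_loss(probs, T))

    def test_penalty_is_squared_frobenius(self):
        probs = np.full((2, 6), 1 / 6)
        T = onehot([0, 5])
        W = np.array([[1.0, 2.0], [0.0, -1.0]])
        loss = cross_entropy_l2_loss(probs, T, weights=W, alpha_r=0.5)
        assert loss == pytest.approx(np.log(6) + 0.5 * 6.0, rel=1e-12)

    def test_validation(self):
        probs = np.full((2, 6), 1 / 6)
        with pytest.raises(ValueError, match="alpha_r"):
            cross_entropy_l2_loss(probs, onehot([0, 1]), alpha_r=-1)
        with pytest.raises(ValueError, match="sum"):
            cross_entropy_l2_loss(probs * 2, onehot([0, 1]))
        with pytest.raises(ValueError, match="shape"):
            cross_entropy_l2_loss(probs, onehot([0, 1, 2]))


class TestELM:
    def test_beta_matches_lstsq_oracle(self, rng):
        X = rng.random((40, 10))
        y = rng.integers(0, 6, 40)
        model = elm_fit(X, y, n_hidden=30, seed=1)
        H = expit(X @ model.hidden_weights_ + model.hidden_bias_)
        T = onehot(np.searchsorted(model.classes_, y), len(model.classes_))
        beta_oracle = np.linalg.lstsq(H, T, rcond=None)[0]
        assert np.linalg.norm(H @ model.beta_ - T) == pytest.approx(
            np.linalg.norm(H @ beta_oracle - T), abs=1e-8)

    def test_square_hidden_interpolates_exactly(self, rng):
        X = rng.random((8, 4))
        y = np.array([0, 1, 2, 3, 4, 5, 0, 1])
        model = ELMClassifier(n_hidden=8, random_state=0).fit(X, y)
        H = expit(X @ model.hidden_weights_ + model.hidden_bias_)
        T = onehot(np.searchsorted(model.classes_, y), len(model.classes_))
        assert np.linalg.norm(H @ model.beta_ - T) < 1e-6
        assert np.array_equal(model.predict(X), y)

    def test_beta_optimal_vs_random_challengers(self, rng):
        X = rng.random((30, 10))
        y = rng.integers(0, 6, 30)
        model = elm_fit(X, y, n_hidden=20, seed=3)
        H = expit(X @ model.hidden_weights_ + model.hidden_bias_)
        T = onehot(np.searchsorted(model.classes_, y), len(model.classes_))
        best = np.linalg.norm(H @ model.beta_ - T)
        for _ in range(20):
            challenger = model.beta_ + rng.normal(0, 0.1, model.beta_.shape)
            assert best <= np.linalg.norm(H @ challenger - T) + 1e-6

    def test_default_width_is_500_sigmoid(self):
        assert ELMClassifier().n_hidden == 500

    def test_constant_hidden_column_warns_but_fits(self, rng):
        X = np.zeros((12, 10))  # all-zero input -> constant hidden columns
        y = np.repeat(np.arange(6), 2)
        with pytest.warns(RuntimeWarning, match="constant"):
            model = ELMClassifier(n_hidden=10, random_state=0).fit(X, y)
        assert hasattr(model, "beta_")

    def test_single_class_predicts_it_everywhere(self, rng):
        X = rng.random((10, 10))
        model = ELMClassifier(n_hidden=12, random_state=0).fit(X, np.full(10, 4))
        assert np.all(model.predict(rng.random((7, 10))) == 4)


class TestKSelection:
    @staticmethod
    def three_clusters(rng, spread=0.05, n=60):
        centers = np.array([[0.0] * 4, [10.0] * 4, [-10.0, 10.0, -10.0, 10.0]])
        X = np.vstack([c + spread * rng.standard_normal((n, 4)) for c in centers])
        y = np.repeat([0, 1, 2], n)
        return X, y

    def test_elbow_at_three_tight_clusters(self, rng):
        X, _ = self.three_clusters(rng)
        k, sse = rbf_select_k(X, k_max=6, seed=0)
        assert k == 3
        assert sse[1] / sse[2] >= 10      # big drop entering k=3
        assert np.all(sse[2:-1] / np.maximum(sse[3:], 1e-12) < 1.5)

    def test_sse_non_increasing(self, rng):
        X = rng.random((50, 5))
        _, sse = rbf_select_k(X, k_max=8, seed=0, n_init=20)
        assert np.all(np.diff(sse) <= 1e-9)

    def test_identical_points_zero_sse(self):
        X = np.tile([1.0, 2.0], (30, 1))
        k, sse = rbf_select_k(X, k_max=5, seed=0)
        assert k == 1
        assert np.all(sse == 0)

    def test_fewer_distinct_points_than_k_raises(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ClusteringError):
            rbf_select_k(X, k_max=3, seed=0)


class TestRBF:
    def test_center_activation_is_one(self, rng):
        X = rng.random((30, 10))
        y = rng.integers(0, 3, 30)
        model = rbf_fit(X, y, k=3, seed=0, max_epochs=5)
        Phi = model._hidden(model.centers_)
        assert np.allclose(np.diag(Phi), 1.0)

    def test_default_k_is_three(self):
        assert RBFNetClassifier().n_centers == 3

    def test_width_modes(self, rng):
        X, y = TestKSelection.three_clusters(rng)
        classical = rbf_fit(X, y, k=3, seed=0, max_epochs=2)
        paper = rbf_fit(X, y, k=3, seed=0, max_epochs=2, width_mode="paper")
        # classical width mu/sqrt(2k) exceeds paper's mu/k at k=3
        assert classical.width_ == pytest.approx(
            paper.width_ * 3 / np.sqrt(6), rel=1e-12)

    def test_single_center_requires_width(self, rng):
        X = rng.random((10, 3))
        y = rng.integers(0, 2, 10)
        with pytest.raises(ValueError, match="width"):
            rbf_fit(X, y, k=1, seed=0, max_epochs=2)
        model = rbf_fit(X, y, k=1, seed=0, max_epochs=2, width=1.0)
        assert model.width_ == 1.0

    def test_recovers_separable_clusters(self, rng):
        X, y = TestKSelection.three_clusters(rng)
        model = rbf_fit(X, y, k=3, seed=0, max_epochs=600)
        Xt, yt = TestKSelection.three_clusters(np.random.default_rng(99))
        assert (model.predict(Xt) == yt).mean() >= 0.95

    def test_lstsq_output_solver(self, rng):
        X, y = TestKSelection.three_clusters(rng)
        model = rbf_fit(X, y, k=3, seed=0, output_solver="lstsq")
        assert (model.predict(X) == y).mean() >= 0.95


class TestBPNN:
    def test_default_architecture(self):
        model = BPNNClassifier()
        assert model.hidden_layer_sizes == (21, 43, 87)
        assert model.max_epochs == 8000

    def test_trained_layer_shapes_and_softmax_output(self, tiny_train_table):
        cfg = TrainConfig(epochs=5, seed=0)
        model = bpnn_train(tiny_train_table, cfg)
        shapes = [l.W.shape for l in model.layers_]
        assert shapes == [(10, 21), (21, 43), (43, 87), (87, 6)]
        assert model.layers_[-1].activation == "softmax"
        probs = model.predict_proba(tiny_train_table.X[:50])
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_training_set(self, rng):
        X = rng.random((30, 10))
        model = BPNNClassifier(max_epochs=10, random_state=0).fit(
            X, np.full(30, 2))
        assert np.all(model.predict(rng.random((9, 10))) == 2)

    def test_label_recovery_on_separable_cohort(self, tiny_train_table,
                                                tiny_test_table):
        model = BPNNClassifier(max_epochs=150, batch_size=128,
                               learning_rate=3e-3, random_state=1)
        model.fit(tiny_train_table.X, tiny_train_table.y)
        acc = (model.predict(tiny_test_table.X) == tiny_test_table.y).mean()
        assert acc >= 0.95

    def test_divergence_raises_with_epoch(self, tiny_train_table):
        with pytest.raises(ConvergenceError, match="epoch"):
            BPNNClassifier(max_epochs=3, learning_rate=1e200,
                           random_state=0).fit(tiny_train_table.X,
                                               tiny_train_table.y)


class TestBPELM:
    def test_beta_matches_lstsq_oracle(self, tiny_train_table):
        cfg = TrainConfig(epochs=10, seed=2, n_random_hidden=60)
        model = bpelm_train(tiny_train_table, cfg)
        from pearnose.networks import LayeredNetParams
        O3 = LayeredNetParams(model.layers_).output(tiny_train_table.X)
        T = onehot(np.searchsorted(model.classes_, tiny_train_table.y),
                   len(model.classes_))
        oracle = np.linalg.lstsq(O3, T, rcond=None)[0]
        assert np.linalg.norm(O3 @ model.beta_ - T) == pytest.approx(
            np.linalg.norm(O3 @ oracle - T), abs=1e-8)

    def test_wide_random_layer_interpolates_tiny_set(self, rng):
        # random-feature width >= N and alpha_r = 0: training accuracy 1.0
        X = rng.random((24, 10))
        y = rng.integers(0, 6, 24)
        model = BPELMClassifier(hidden_layer_sizes=(16,), n_random_hidden=64,
                                alpha=0.0, max_epochs=20, random_state=0)
        model.fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_random_layer_frozen_through_training(self, tiny_train_table):
        for mode in ("softmax-head", "through-frozen"):
            cfg = TrainConfig(epochs=8, seed=4, n_random_hidden=40,
                              pretrain_mode=mode)
            model = bpelm_train(tiny_train_table, cfg)
            W0, b0 = model.random_hidden_init_
            assert np.array_equal(model.layers_[-1].W, W0)
            assert np.array_equal(model.layers_[-1].b, b0)
            assert model.layers_[-1].trainable is False
            assert model.layers_[-1].activation == "sigmoid"

    def test_seed_determinism(self, tiny_train_table, tiny_test_table):
        preds = []
        for _ in range(2):
            cfg = TrainConfig(epochs=10, seed=3, n_random_hidden=50)
            model = bpelm_train(tiny_train_table, cfg)
            preds.append(model.predict(tiny_test_table.X))
        assert np.array_equal(preds[0], preds[1])

    def test_label_recovery_on_separable_cohort(self, tiny_train_table,
                                                tiny_test_table):
        cfg = TrainConfig(epochs=40, batch_size=128, seed=0)
        model = bpelm_train(tiny_train_table, cfg)
        labels, probs = net_predict(model, tiny_test_table.X)
        assert (labels == tiny_test_table.y).mean() >= 0.95
        assert probs.shape == (len(tiny_test_table), 6)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestSerialization:
    @pytest.mark.parametrize("maker", [
        lambda t: BPNNClassifier(max_epochs=5, random_state=0).fit(t.X, t.y),
        lambda t: ELMClassifier(n_hidden=40, random_state=0).fit(t.X, t.y),
        lambda t: RBFNetClassifier(max_epochs=5, random_state=0).fit(t.X, t.y),
        lambda t: BPELMClassifier(max_epochs=5, n_random_hidden=40,
                                  random_state=0).fit(t.X, t.y),
    ], ids=["bpnn", "elm", "rbf", "bpelm"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, maker,
                                                   tiny_train_table,
                                                   tiny_test_table):
        model = maker(tiny_train_table)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.predict(tiny_test_table.X),
                              model.predict(tiny_test_table.X))
        np.testing.assert_allclose(back.predict_proba(tiny_test_table.X),
                                   model.predict_proba(tiny_test_table.X),
                                   rtol=1e-12, atol=1e-15)
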