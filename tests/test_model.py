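"""Classifier internals: softmax, penalized objective, gradients, training."""

import math

import numpy as np
import pytest

from dtiscope.model import (
    DTIClassifier,
    DTIClassifierResults,
    NetworkConfig,
    TrainConfig,
    penalized_cross_entropy,
    softmax,
    _forward,
    _init_params,
    _loss_and_grads,
)


class TestSoftmax:
    def test_symmetric_logits(self):
        np.testing.assert_allclose(softmax([[0.0, 0.0]]), [[0.5, 0.5]])

    @pytest.mark.parametrize("shift", [-3.0, 0.0, 5.0, 700.0])
    def test_shift_invariance(self, shift):
        z = np.array([[0.3, -1.2], [2.0, 2.5]])
        np.testing.assert_allclose(softmax(z + shift), softmax(z), atol=1e-12)

    def test_rows_normalized_for_random_logits(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.standard_normal((200, 2)) * 50)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert (p >= 0).all()


class TestForward:
    def test_hand_computed_toy_network(self):
        """2-feature net, one hidden unit, weights set by hand."""
        net = NetworkConfig(layer_sizes=(2, 1, 2), dropout_rate=0.0)
        params = [
            (np.array([[0.5], [0.25]]), np.array([0.1])),
            (np.array([[0.3, -0.7]]), np.array([0.05, -0.05])),
        ]
        x = np.array([[1.0, -2.0]])
        cm, _, _ = _forward(params, x, net)
        h = max(0.0, 1.0 * 0.5 + (-2.0) * 0.25 + 0.1)  # 0.1
        z0, z1 = h * 0.3 + 0.05, h * (-0.7) - 0.05
        denom = math.exp(z0) + math.exp(z1)
        np.testing.assert_allclose(
            cm, [[math.exp(z0) / denom, math.exp(z1) / denom]], atol=1e-12
        )

    def test_width_mismatch_rejected(self):
        net = NetworkConfig(layer_sizes=(4, 3, 2))
        params = _init_params(net, np.random.default_rng(0))
        with pytest.raises(ValueError):
            _forward(params, np.zeros((1, 5)), net)

    def test_inference_is_deterministic_without_dropout_rng(self):
        net = NetworkConfig(layer_sizes=(6, 4, 2), dropout_rate=0.5)
        params = _init_params(net, np.random.default_rng(1))
        X = np.random.default_rng(2).standard_normal((10, 6))
        a, _, _ = _forward(params, X, net)
        b, _, _ = _forward(params, X, net)
        np.testing.assert_array_equal(a, b)


class TestLoss:
    def test_perfect_positive_is_zero(self):
        assert penalized_cross_entropy(
            np.array([[0.0, 1.0]]), np.array([1]), eta=37.0
        ) == pytest.approx(0.0, abs=1e-6)

    def test_confident_negative_with_penalty(self):
        loss = penalized_cross_entropy(np.array([[1.0, 0.0]]), np.array([0]), eta=10.0)
        assert loss == pytest.approx(-10.0, abs=1e-6)

    def test_matches_independent_scalar_reimplementation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=6)
        cm = np.column_stack([1 - p, p])
        y = np.array([1, 0, 1, 0, 0, 1])
        eta, eps = 3.5, 1e-7

        total = 0.0
        for i in range(6):
            pi = min(max(p[i], eps), 1 - eps)
            total += -y[i] * math.log(pi) - (1 - y[i]) * math.log(1 - pi)
            if y[i] == 0:
                total -= eta * abs(cm[i, 0])
        expected = total / 6
        assert penalized_cross_entropy(cm, y, eta, eps) == pytest.approx(
            expected, abs=1e-10
        )

    def test_eta_zero_is_plain_cross_entropy(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, size=8)
        cm = np.column_stack([1 - p, p])
        y = rng.integers(0, 2, size=8)
        plain = float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))
        assert penalized_cross_entropy(cm, y, eta=0.0) == pytest.approx(plain, abs=1e-10)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            penalized_cross_entropy(np.array([[0.5, 0.5]]), np.array([2]), 1.0)


class TestGradients:
    def test_analytic_gradient_matches_central_differences(self):
        """Backprop gradients of the penalized objective vs numerical
        differentiation, relative tolerance 1e-4, on a 5-sample toy batch."""
        net = NetworkConfig(layer_sizes=(4, 3, 2), dropout_rate=0.0)
        tc = TrainConfig(eta=7.0, seed=0)
        rng = np.random.default_rng(11)
        params = _init_params(net, rng)
        X = rng.standard_normal((5, 4))
        y = np.array([1, 0, 0, 1, 0])

        def loss_at(params_flat):
            cm, _, _ = _forward(params_flat, X, net)
            return penalized_cross_entropy(cm, y, tc.eta, tc.prob_floor)

        _, grads = _loss_and_grads(params, X, y, net, tc, dropout_rng=None)
        h = 1e-6
        for li in range(len(params)):
            for which in (0, 1):  # weight, bias
                arr = params[li][which]
                g = grads[li][which]
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    pp = [(W.copy(), b.copy()) for W, b in params]
                    pp[li][which][idx] += h
                    up = loss_at(pp)
                    pp[li][which][idx] -= 2 * h
                    down = loss_at(pp)
                    num = (up - down) / (2 * h)
                    denom = max(abs(num), abs(g[idx]), 1e-8)
                    assert abs(num - g[idx]) / denom < 1e-4


def two_blob_data(rng, n_pos=30, n_neg=60, dim=8):
    Xp = rng.standard_normal((n_pos, dim)) + 1.2
    Xn = rng.standard_normal((n_neg, dim)) - 1.2
    X = np.vstack([Xp, Xn])
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


class TestTraining:
    def test_same_seed_reproduces_weights_exactly(self):
        rng = np.random.default_rng(3)
        X, y = two_blob_data(rng)
        net = NetworkConfig(layer_sizes=(8, 6, 2), dropout_rate=0.5)
        tc = TrainConfig(eta=1.0, learning_rate=1e-3, epochs=20, batch_size=16, seed=4)
        r1 = DTIClassifier(X, y, network=net, train=tc).fit()
        r2 = DTIClassifier(X, y, network=net, train=tc).fit()
        for (W1, b1), (W2, b2) in zip(r1.params, r2.params):
            np.testing.assert_array_equal(W1, W2)
            np.testing.assert_array_equal(b1, b2)

    def test_single_class_rejected(self):
        X = np.zeros((5, 4))
        with pytest.raises(ValueError):
            DTIClassifier(X, np.ones(5, dtype=int))

    def test_learns_separable_blobs(self):
        rng = np.random.default_rng(8)
        X, y = two_blob_data(rng, n_pos=60, n_neg=120)
        net = NetworkConfig(layer_sizes=(8, 6, 2), dropout_rate=0.2)
        tc = TrainConfig(eta=0.0, learning_rate=1e-2, epochs=120, batch_size=32,
                         seed=0, patience=0)
        res = DTIClassifier(X, y, network=net, train=tc).fit()
        assert res.history["train_accuracy"][-1] > 0.95

    def test_penalty_depresses_negative_class_probability(self):
        """Raising the negative-class penalty weight over {0, 10, 100} does not
        increase the mean positive-class probability on true negatives."""
        means = {0.0: [], 10.0: [], 100.0: []}
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, y = two_blob_data(rng, n_pos=25, n_neg=50)
            for eta in means:
                tc = TrainConfig(eta=eta, learning_rate=1e-2, epochs=60,
                                 batch_size=25, seed=seed, patience=0)
                net = NetworkConfig(layer_sizes=(8, 6, 2), dropout_rate=0.2)
                res = DTIClassifier(X, y, network=net, train=tc).fit()
                p_neg = res.predict_proba(X[y == 0])[:, 1]
                means[eta].append(p_neg.mean())
        m0, m10, m100 = (float(np.mean(means[e])) for e in (0.0, 10.0, 100.0))
        assert m0 >= m10 >= m100

    def test_history_lengths_match_epochs(self):
        rng = np.random.default_rng(12)
        X, y = two_blob_data(rng, n_pos=10, n_neg=20)
        tc = TrainConfig(epochs=7, batch_size=10, seed=1, patience=0)
        res = DTIClassifier(X, y, network=NetworkConfig(layer_sizes=(8, 4, 2)),
                            train=tc).fit()
        assert len(res.history["loss"]) == 7
        assert len(res.history["train_accuracy"]) == 7


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(2)
        X, y = two_blob_data(rng)
        tc = TrainConfig(epochs=15, batch_size=16, seed=0)
        return DTIClassifier(X, y, network=NetworkConfig(layer_sizes=(8, 5, 2)),
                             train=tc).fit()

    def test_repeatable(self, fitted):
        X = np.random.default_rng(7).standard_normal((20, 8))
        np.testing.assert_array_equal(fitted.predict_proba(X), fitted.predict_proba(X))

    def test_rows_sum_to_one(self, fitted):
        X = np.random.default_rng(8).standard_normal((1000, 8)) * 10
        cm = fitted.predict_proba(X)
        np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_equivariance(self, fitted):
        X = np.random.default_rng(9).standard_normal((30, 8))
        perm = np.random.default_rng(10).permutation(30)
        np.testing.assert_allclose(
            fitted.predict_proba(X)[perm], fitted.predict_proba(X[perm]), atol=1e-12
        )

    def test_save_load_round_trip(self, fitted, tmp_path):
        path = tmp_path / "model.npz"
        fitted.save(path)
        back = DTIClassifierResults.load(path)
        X = np.random.default_rng(11).standard_normal((12, 8))
        np.testing.assert_allclose(
            back.predict_proba(X), fitted.predict_proba(X), atol=1e-12
        )

    def test_summary_mentions_architecture(self, fitted):
        assert "8-5-2" in fitted.summary()
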