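"""CNN forward pass, gradients, training, and evaluation bookkeeping."""

import numpy as np
import pytest

import hybridbci as hb
from hybridbci.classifier import (CNNClassifier, conv2d_valid, max_pool_2x2,
                                  mse_loss_and_grad, _backward_pass,
                                  _forward_pass)
from hybridbci.sim import LABELS


class TestForwardPrimitives:
    def test_valid_convolution_hand_example(self):
        X = np.array([[[1., 2., 3.], [4., 5., 6.], [7., 8., 9.]]])
        k = np.array([[[1., 0.], [0., 1.]]])
        out = conv2d_valid(X, k, np.zeros(1))
        assert np.array_equal(out[0, 0], [[6., 8.], [12., 14.]])

    def test_max_pool_of_hand_example(self):
        conv = np.array([[[[6., 8.], [12., 14.]]]])
        pooled, mask = max_pool_2x2(conv)
        assert pooled.shape == (1, 1, 1, 1)
        assert pooled[0, 0, 0, 0] == 14.0
        assert mask[0, 0, 1, 1]

    def test_pool_drops_odd_trailing_edges(self):
        A = np.arange(2 * 3 * 5 * 7, dtype=float).reshape(2, 3, 5, 7)
        pooled, _ = max_pool_2x2(A)
        assert pooled.shape == (2, 3, 2, 3)

    def test_zero_map_zero_weights_gives_zero_scores(self):
        model = CNNClassifier(n_kernels=2, fc1_units=4)
        model.initialize((6, 10), classes=["a", "b", "c"])
        for key in model._PARAM_KEYS:
            setattr(model, key + "_", np.zeros_like(getattr(model, key + "_")))
        scores = model.decision_function(np.zeros((1, 6, 10)))
        assert np.all(scores == 0.0)
        # argmax tie-break: first class
        assert model.predict(np.zeros((1, 6, 10)))[0] == "a"


class TestGradients:
    def test_analytic_matches_central_differences(self):
        """Backprop gradients agree with finite differences to 1e-5."""
        rng = np.random.default_rng(0)
        model = CNNClassifier(n_kernels=2, fc1_units=5, dtype="float64",
                              random_state=0)
        model.initialize((6, 9), classes=[0, 1, 2])
        params = model._params()
        X = rng.standard_normal((4, 6, 9))
        targets = np.eye(3)[rng.integers(0, 3, 4)]

        def loss_fn(p):
            scores = _forward_pass(p, X)
            return mse_loss_and_grad(scores, targets)[0]

        scores, cache = _forward_pass(params, X, want_cache=True)
        _, dscores = mse_loss_and_grad(scores, targets)
        grads = _backward_pass(params, cache, dscores)

        h = 1e-6
        for key in model._PARAM_KEYS:
            num = np.zeros_like(params[key])
            flat = params[key].ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + h
                up = loss_fn(params)
                flat[i] = orig - h
                down = loss_fn(params)
                flat[i] = orig
                num.ravel()[i] = (up - down) / (2 * h)
            denom = max(np.abs(num).max(), np.abs(grads[key]).max(), 1e-12)
            rel = np.abs(grads[key] - num).max() / denom
            assert rel <= 1e-5, f"{key}: relative error {rel}"


class TestTraining:
    def _toy_maps(self, n_per_class=20, seed=0):
        """Two linearly separable classes of 4×4 maps."""
        rng = np.random.default_rng(seed)
        X, y = [], []
        for label, corner in (("left", (0, 0)), ("right", (2, 2))):
            for _ in range(n_per_class):
                m = 0.05 * rng.random((4, 4))
                m[corner[0]:corner[0] + 2, corner[1]:corner[1] + 2] += 1.0
                X.append(m)
                y.append(label)
        return np.stack(X), np.array(y)

    def test_separable_toy_problem_converges(self):
        X, y = self._toy_maps()
        model = CNNClassifier(n_kernels=4, fc1_units=8, n_epochs=200,
                              batch_size=8, random_state=0)
        model.fit(X, y)
        assert model.loss_history_[-1] < model.loss_history_[0]
        assert np.mean(model.predict(X) == y) == 1.0

    def test_default_split_sizes(self, default_config):
        """The stratified 80/20 split of 800 trials is 640/160."""
        maps = np.random.default_rng(0).random((800, 6, 10)).astype("float32")
        y = np.repeat(LABELS, 100)
        result = hb.train(maps, y, hb.TrainConfig(epochs=1))
        assert len(result.y_train) == 640
        assert len(result.y_test) == 160
        # split is stratified: 20 test samples per class
        _, counts = np.unique(result.y_test, return_counts=True)
        assert set(counts) == {20}

    def test_single_class_rejected(self):
        X = np.zeros((10, 4, 4))
        with pytest.raises(ValueError, match="two classes"):
            hb.train(X, ["a"] * 10)

    def test_determinism_same_seed_identical_weights(self):
        X, y = self._toy_maps()
        m1 = CNNClassifier(n_epochs=5, random_state=3).fit(X, y)
        m2 = CNNClassifier(n_epochs=5, random_state=3).fit(X, y)
        for key in m1._PARAM_KEYS:
            assert np.array_equal(getattr(m1, key + "_"),
                                  getattr(m2, key + "_"))

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        X, y = self._toy_maps()
        model = CNNClassifier(n_epochs=50, learning_rate=1e6, random_state=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            model.fit(X, y)

    def test_shape_mismatch_names_expected_and_got(self):
        X, y = self._toy_maps()
        model = CNNClassifier(n_epochs=1, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match=r"\(4, 4\)"):
            model.predict(np.zeros((1, 5, 5)))


class TestEvaluate:
    @pytest.fixture()
    def perfect_toy(self):
        X, y = TestTraining()._toy_maps()
        model = CNNClassifier(n_kernels=4, fc1_units=8, n_epochs=200,
                              batch_size=8, random_state=0).fit(X, y)
        return model, X, y

    def test_all_correct_gives_zero_error(self, perfect_toy):
        model, X, y = perfect_toy
        rep = hb.evaluate(model, X, y)
        assert rep.error_rate == 0.0
        assert rep.accuracy == 100.0

    def test_error_rate_definition(self, perfect_toy):
        """4 wrong out of 160: ε = 0.025, accuracy 97.5 %."""
        model, X, y = perfect_toy
        X160 = np.tile(X, (4, 1, 1))
        y160 = np.tile(y, 4).astype(object)
        wrong = np.flatnonzero(y160 == "left")[:4]
        y160[wrong] = "right"  # mislabel 4 of 160
        rep = hb.evaluate(model, X160, y160)
        assert rep.n_test == 160
        assert rep.error_rate == pytest.approx(0.025)
        assert rep.accuracy == pytest.approx(97.5)

    def test_confusion_identities(self, perfect_toy):
        model, X, y = perfect_toy
        rep = hb.evaluate(model, X, y)
        assert rep.confusion.sum() == len(y)
        # diagonal sum / total = 1 − ε ; accuracy + 100 ε = 100
        assert np.trace(rep.confusion) / rep.confusion.sum() \
            == pytest.approx(1 - rep.error_rate)
        assert rep.accuracy + 100 * rep.error_rate == pytest.approx(100.0)
        # row sums are per-class test counts
        assert rep.confusion.sum(axis=1).tolist() == [20, 20]

    def test_empty_test_set_rejected(self, perfect_toy):
        model, X, _ = perfect_toy
        with pytest.raises(ValueError, match="empty"):
            hb.evaluate(model, X[:0], [])

    def test_unknown_labels_rejected(self, perfect_toy):
        model, X, _ = perfect_toy
        with pytest.raises(ValueError, match="outside"):
            hb.evaluate(model, X[:2], ["left", "mystery"])


class TestEndToEndDecoding:
    def test_high_snr_ssvep_epoch_decodes_to_its_class(self, small_trained):
        model = small_trained["model"]
        cfg = hb.SignalModelConfig(snr_db=20.0)
        ep = hb.make_ssvep_epoch(12.0, cfg, 11)
        assert hb.predict_epoch(model, ep) == "ssvep_12"

    def test_double_blink_epoch_decodes_to_double(self, small_trained):
        model = small_trained["model"]
        ep = hb.make_blink_epoch("double", hb.SignalModelConfig(), 11)
        assert hb.predict_epoch(model, ep) == "blink_double"

    def test_untrained_model_returns_some_valid_label(self, default_config):
        model = CNNClassifier(random_state=1)
        model.initialize((25, 500), classes=list(LABELS))
        ep = hb.make_ssvep_epoch(10.0, default_config, 0)
        assert hb.predict_epoch(model, ep) in LABELS

    def test_training_loss_decreases_on_synthetic_task(self, small_trained):
        hist = small_trained["model"].loss_history_
        assert np.mean(hist[-5:]) < np.mean(hist[:5])

    def test_small_model_generalizes(self, small_trained):
        # sanity floor for the shared fixture, well below the full-run target
        assert small_trained["report"].accuracy >= 70.0
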