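"""CNN stage classifier: building blocks, architecture, training loop."""

import numpy as np
import pytest

from pulmostage.mcnn import (
    MCNNConfig,
    build_mcnn,
    cross_entropy,
    lr_schedule,
    predict,
    relu,
    softmax,
    train,
    _one_hot,
)

TINY = dict(input_shape=(16, 16, 1), n_blocks=2, channel_progression=(3, 4),
            fc_units=8, n_classes=3, dropout_rate=0.0)


class TestElementaryOps:
    @pytest.mark.parametrize("x,expected", [(-2.0, 0.0), (5.0, 5.0), (0.0, 0.0)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_cross_entropy_perfect_prediction(self):
        z = np.array([[0, 1, 0]])
        p = np.array([[0.0, 1.0, 0.0]])
        assert cross_entropy(z, p) == pytest.approx(0.0, abs=1e-9)

    def test_cross_entropy_uniform_is_log_m(self):
        m = 7
        z = _one_hot(np.array([3]), m)
        p = np.full((1, m), 1 / m)
        assert cross_entropy(z, p) == pytest.approx(np.log(m), abs=1e-12)

    def test_cross_entropy_loop_oracle(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(12, 5))
        p = softmax(logits)
        y = rng.integers(0, 5, 12)
        z = _one_hot(y, 5)
        manual = np.mean([-np.log(p[i, y[i]]) for i in range(12)])
        assert cross_entropy(z, p) == pytest.approx(manual, abs=1e-10)

    def test_cross_entropy_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="probability"):
            cross_entropy(np.array([[1, 0]]), np.array([[0.9, 0.3]]))

    @pytest.mark.parametrize("epoch,factor", [(0, 1), (9, 1), (10, 10),
                                              (19, 10), (25, 100), (59, 100000)])
    def test_lr_schedule(self, epoch, factor):
        assert lr_schedule(epoch, 0.01) == pytest.approx(0.01 / factor)


class TestArchitecture:
    def test_default_spatial_reduction(self):
        cfg = MCNNConfig()
        assert cfg.spatial_after_pooling == (4, 4)

    def test_small_input_reduces_to_one(self):
        cfg = MCNNConfig(input_shape=(64, 64, 8),
                         channel_progression=(4, 4, 8, 8, 16, 16), fc_units=64)
        assert cfg.spatial_after_pooling == (1, 1)

    def test_spatial_collapse_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            MCNNConfig(input_shape=(16, 16, 1))  # 6 blocks cannot pool 16 six times

    @pytest.mark.parametrize("n_blocks", [1, 2, 3, 4, 5, 6])
    def test_block_sweep_supported(self, n_blocks):
        cfg = MCNNConfig(input_shape=(64, 64, 2), n_blocks=n_blocks,
                         channel_progression=(2, 2, 4, 4, 8, 8)[:n_blocks],
                         fc_units=8, n_classes=4)
        model = build_mcnn(cfg)
        probs = model.forward(np.zeros((2, 2, 64, 64), dtype=np.float32))
        assert probs.shape == (2, 4)

    def test_parameter_count_deterministic(self):
        cfg = MCNNConfig(**TINY, seed=1)
        assert build_mcnn(cfg).parameter_count == build_mcnn(cfg).parameter_count


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        cfg = MCNNConfig(input_shape=(8, 8, 2), n_blocks=2,
                         channel_progression=(3, 4), fc_units=5, n_classes=3,
                         dropout_rate=0.0, dtype="float64", seed=3)
        model = build_mcnn(cfg)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 2, 8, 8))
        y = rng.integers(0, 3, 4)
        onehot = _one_hot(y, 3)
        cache = {}
        model.forward(x, cache=cache)
        grads = model.backward(cache, onehot)
        params = model.parameters
        eps = 1e-6
        for pi in range(len(params)):
            p, g = params[pi], grads[pi]
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                up = cross_entropy(onehot, model.forward(x))
                p[idx] = old - eps
                down = cross_entropy(onehot, model.forward(x))
                p[idx] = old
                numeric = (up - down) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, abs=1e-5, rel=1e-5)


class TestTraining:
    def _toy_data(self, n=30, seed=0):
        """Two linearly separable blob sizes on 16x16 frames."""
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for i in range(n):
            img = np.zeros((16, 16), dtype=np.float32)
            r = 2 if i % 2 == 0 else 5
            cy, cx = rng.integers(6, 10, 2)
            rr, cc = np.indices((16, 16))
            img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r ** 2] = 1.0
            xs.append(img[None])
            ys.append(i % 2)
        return np.stack(xs), np.array(ys)

    def _config(self, **kw):
        base = dict(input_shape=(16, 16, 1), n_blocks=2, channel_progression=(4, 8),
                    fc_units=16, n_classes=2, dropout_rate=0.0, lr0=0.05,
                    batch_size=10, epochs=5, seed=2)
        base.update(kw)
        return MCNNConfig(**base)

    def test_separable_problem_reaches_perfect_validation(self):
        x, y = self._toy_data(60)
        cfg = self._config()
        model = build_mcnn(cfg)
        model, hist = train(model, (x[:40], y[:40]), cfg,
                            validation_data=(x[40:], y[40:]))
        assert max(hist.val_accuracy) == 1.0

    def test_initial_loss_near_log_n_classes(self):
        cfg = MCNNConfig(input_shape=(16, 16, 1), n_blocks=2,
                         channel_progression=(3, 4), fc_units=8, n_classes=5,
                         dropout_rate=0.0, seed=0)
        model = build_mcnn(cfg)
        x = np.random.default_rng(0).normal(size=(20, 1, 16, 16)).astype(np.float32)
        probs = model.forward(x)
        loss = cross_entropy(_one_hot(np.zeros(20, int), 5), probs)
        assert loss == pytest.approx(np.log(5), rel=0.05)

    def test_training_bit_reproducible(self):
        x, y = self._toy_data(30)
        for _ in range(2):
            cfg = self._config(epochs=3)
            model = build_mcnn(cfg)
            model, hist = train(model, (x, y), cfg)
            try:
                ref_loss
            except NameError:
                ref_loss = hist.train_loss
                ref_params = [p.copy() for p in model.parameters]
            else:
                assert hist.train_loss == ref_loss
                assert all(np.array_equal(a, b)
                           for a, b in zip(ref_params, model.parameters))

    def test_history_lr_matches_schedule(self):
        x, y = self._toy_data(20)
        cfg = self._config(epochs=25, lr0=0.03)
        model = build_mcnn(cfg)
        _, hist = train(model, (x, y), cfg)
        expected = [lr_schedule(e, 0.03) for e in range(25)]
        assert hist.learning_rate == expected

    def test_early_stopping_restores_best(self):
        x, y = self._toy_data(40)
        cfg = self._config(epochs=40, early_stopping_patience=3, lr0=0.2)
        model = build_mcnn(cfg)
        _, hist = train(model, (x[:30], y[:30]), cfg,
                        validation_data=(x[30:], y[30:]))
        assert len(hist.train_loss) < 40  # stopped early

    def test_empty_class_in_split_rejected(self):
        x, y = self._toy_data(20)
        cfg = self._config(n_classes=3)
        model = build_mcnn(cfg)
        with pytest.raises(ValueError, match="empty classes"):
            train(model, (x, y), cfg, validation_data=(x, y))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        from pulmostage.mcnn import load_model, save_model

        cfg = MCNNConfig(**TINY, seed=8)
        model = build_mcnn(cfg, class_names=["x", "y", "z"])
        model.input_mean, model.input_std = 3.5, 2.0
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.config == cfg
        assert back.class_names == ["x", "y", "z"]
        assert (back.input_mean, back.input_std) == (3.5, 2.0)
        x = np.random.default_rng(0).normal(size=(3, 1, 16, 16)).astype(np.float32)
        assert np.array_equal(model.forward(x), back.forward(x))


class TestPredict:
    def test_probabilities_normalized_and_named(self):
        cfg = MCNNConfig(**TINY, seed=0)
        model = build_mcnn(cfg, class_names=["a", "b", "c"])
        probs, label = predict(model, np.zeros((16, 16, 1)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert label in ("a", "b", "c")

    def test_untrained_model_near_uniform(self):
        cfg = MCNNConfig(**TINY, seed=5)
        model = build_mcnn(cfg)
        rng = np.random.default_rng(0)
        maxes = [predict(model, rng.normal(size=(16, 16, 1)))[0].max()
                 for _ in range(20)]
        assert np.mean(maxes) < 2 / 3

    def test_shape_mismatch_rejected(self):
        model = build_mcnn(MCNNConfig(**TINY, seed=0))
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((10, 10, 1)))
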