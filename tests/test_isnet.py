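"""ISNet-1D: architecture, gradients, loss, training contracts."""

import numpy as np
import pytest

from vibrofirm import isnet1d as nn
from vibrofirm.isnet1d import (ISNetConfig, ISNetError, TrainConfig,
                               TrainingDivergedError, build_isnet, loss_eq1,
                               predict, train)

TINY = ISNetConfig(input_length=64, stem_filters=4, branch_filters=(3, 3, 3, 3),
                   se_reduction=4, post_filters=6, fc_units=8, dropout=0.0)


def default_param_count(c: ISNetConfig) -> int:
    """Independent per-layer hand count of trainable parameters."""
    n = 0
    n += (1 * c.stem_kernel + 1) * c.stem_filters            # stem conv
    n += 2 * c.stem_filters                                  # batch norm
    cin = c.stem_filters
    b1, b2, b3, b4 = c.branch_filters
    n += (cin + 1) * b1                                      # branch 1: 1x1
    n += (cin + 1) * b2 + (b2 * 3 + 1) * b2                  # branch 2: 1x1+k3
    n += (cin + 1) * b3 + (b3 * 5 + 1) * b3                  # branch 3: 1x1+k5
    n += (cin + 1) * b4                                      # branch 4: pool+1x1
    cat = sum(c.branch_filters)
    cr = cat // c.se_reduction
    n += (cat + 1) * cr + (cr + 1) * cat                     # SE excitation
    n += (cat * c.post_kernel + 1) * c.post_filters          # final conv
    flat = c.post_filters * (c.input_length // c.pool_size // c.pool_size)
    n += (flat + 1) * c.fc_units                             # fc1
    n += (c.fc_units + 1) * c.output_dim                     # output
    return n


class TestArchitecture:
    def test_forward_well_posed_on_zero_input(self):
        net = build_isnet(ISNetConfig(), seed=0)
        out = net.forward(np.zeros(2623))
        assert out.shape == (1, 1)
        assert np.isfinite(out).all()

    def test_wrong_input_length_rejected(self):
        net = build_isnet(TINY, seed=0)
        with pytest.raises(ISNetError):
            net.forward(np.zeros(65))

    def test_parameter_count_matches_hand_count(self):
        for cfg in (ISNetConfig(), TINY):
            net = build_isnet(cfg, seed=0)
            assert net.n_parameters() == default_param_count(cfg)

    def test_default_config_matches_published_hyperparameters(self):
        """Audit: stem 16@k3, four branches, 32@k5, FC 64, dropout 0.3,
        input 2623; schedule 16 / 1e-4 / x0.1 per 50 / lambda 1e-4 / 300."""
        c = ISNetConfig()
        assert (c.input_length, c.stem_filters, c.stem_kernel) == (2623, 16, 3)
        assert len(c.branch_filters) == 4
        assert (c.post_filters, c.post_kernel) == (32, 5)
        assert (c.fc_units, c.dropout, c.output_dim) == (64, 0.3, 1)
        t = TrainConfig()
        assert (t.batch_size, t.initial_lr) == (16, 1e-4)
        assert (t.lr_drop_factor, t.lr_drop_period) == (0.1, 50)
        assert (t.l2_lambda, t.max_epochs) == (1e-4, 300)

    def test_se_gates_strictly_inside_unit_interval(self):
        net = build_isnet(TINY, seed=1)
        se = net.layer("se")
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 12, 16))
        gates = se.gates(x)
        assert np.all(gates > 0) and np.all(gates < 1)

    def test_gradients_match_numeric_differentiation(self):
        """End-to-end analytic gradients vs central differences (float64)."""
        cfg = ISNetConfig(input_length=40, stem_filters=3,
                          branch_filters=(2, 2, 2, 2), se_reduction=2,
                          post_filters=4, fc_units=5, dropout=0.0)
        net = build_isnet(cfg, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 40))
        y = rng.standard_normal(3)

        def loss():
            out = net.forward(x, train=True, dtype=np.float64)
            return float(np.mean((np.ravel(out) - y) ** 2))

        net.zero_grads()
        out = net.forward(x, train=True, dtype=np.float64)
        net.backward((2.0 / 3) * (np.ravel(out) - y)[:, None])
        eps = 1e-6
        for p in net.params():
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), p.name


class TestLoss:
    def test_perfect_fit_without_penalty_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert loss_eq1(y, y, (), 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert loss_eq1([0.0], [2.0], (), 0.0) == pytest.approx(4.0)
        # perfect fit, lambda=2, weights (1, 1): 0 + 0.5*2*2 = 2
        assert loss_eq1([1.0], [1.0], [np.array([1.0, 1.0])], 2.0) == \
            pytest.approx(2.0)

    def test_zero_lambda_equals_mse(self):
        rng = np.random.default_rng(0)
        y, yhat = rng.standard_normal(50), rng.standard_normal(50)
        assert loss_eq1(y, yhat, [np.ones(5)], 0.0) == \
            pytest.approx(np.mean((y - yhat) ** 2))

    def test_network_weights_only_penalized(self):
        """Biases and batch-norm parameters are excluded from the penalty."""
        net = build_isnet(TINY, seed=0)
        manual = sum(float(np.sum(p.value.astype(np.float64) ** 2))
                     for p in net.params() if p.kind == "weight")
        y = np.array([1.0, 2.0])
        got = loss_eq1(y, y, net, 2.0)
        assert got == pytest.approx(manual)

    def test_empty_vectors_rejected(self):
        with pytest.raises(ISNetError):
            loss_eq1([], [], (), 0.0)


def _toy_data(n=10, length=64, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, length))
    y = X[:, :8].mean(axis=1) * 3.0 + 2.0
    return X, y


class TestTraining:
    def test_memorizes_tiny_training_set(self):
        """Overfit-capacity probe: validation = training, loss collapses."""
        X, y = _toy_data(10)
        net = build_isnet(TINY, seed=0)
        cfg = TrainConfig(batch_size=5, initial_lr=3e-3, max_epochs=200,
                          early_stopping_patience=200, l2_lambda=0.0, seed=0)
        trained, hist = train(net, X, y, X, y, cfg, isnet_config=TINY)
        assert hist.train_loss[trained.best_epoch - 1] < \
            0.05 * hist.train_loss[0]

    def test_best_epoch_attains_minimum_validation_loss(self):
        X, y = _toy_data(16)
        net = build_isnet(TINY, seed=1)
        cfg = TrainConfig(batch_size=8, initial_lr=1e-3, max_epochs=30,
                          early_stopping_patience=30, seed=1)
        trained, hist = train(net, X[:12], y[:12], X[12:], y[12:], cfg)
        assert hist.val_loss[trained.best_epoch - 1] == min(hist.val_loss)

    def test_training_is_deterministic(self):
        X, y = _toy_data(12)
        histories = []
        for _ in range(2):
            net = build_isnet(TINY, seed=2)
            cfg = TrainConfig(batch_size=4, initial_lr=1e-3, max_epochs=10,
                              early_stopping_patience=10, seed=2)
            _, hist = train(net, X[:8], y[:8], X[8:], y[8:], cfg)
            histories.append(hist)
        np.testing.assert_allclose(histories[0].val_loss,
                                   histories[1].val_loss, atol=1e-6)
        np.testing.assert_allclose(histories[0].train_loss,
                                   histories[1].train_loss, atol=1e-6)

    def test_divergence_raises(self):
        X, y = _toy_data(8)
        net = build_isnet(TINY, seed=0)
        cfg = TrainConfig(batch_size=4, initial_lr=1e10, max_epochs=20,
                          early_stopping_patience=20, seed=0)
        with pytest.raises(TrainingDivergedError):
            train(net, X, 1e30 * y, X, 1e30 * y, cfg)


class TestPredict:
    def test_single_equals_batched(self):
        net = build_isnet(TINY, seed=3)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((7, 64))
        batched = predict(net, X)
        singles = np.array([predict(net, X[i])[0] for i in range(7)])
        np.testing.assert_allclose(batched, singles, atol=1e-6)

    def test_zeroed_output_layer_predicts_bias(self):
        net = build_isnet(TINY, seed=4)
        out = net.layer("out")
        out.W.value[...] = 0.0
        out.b.value[...] = 1.75
        X = np.random.default_rng(1).standard_normal((5, 64))
        np.testing.assert_allclose(predict(net, X), 1.75, atol=1e-6)
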