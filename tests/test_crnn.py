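"""Feature-extractor tests: each layer against brute-force oracles, plus
parameter accounting and training determinism."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from memoaffect import crnn


class TestOutputLength:
    @pytest.mark.parametrize(
        "v,p,k,sl,expected",
        [(128, 0, 8, 1, 121), (128, 0, 2, 1, 127), (128, 7, 8, 1, 128)],
    )
    def test_published_lengths(self, v, p, k, sl, expected):
        assert crnn.output_length(v, p, k, sl) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError):
            crnn.output_length(4, 0, 8, 1)
        with pytest.raises(ValueError):
            crnn.output_length(128, 0, 8, 0)


class TestConv1dSame:
    def test_zero_input_yields_bias(self):
        w = np.zeros((16, 8))
        b = np.zeros(16)
        b[0] = 0.5
        out = crnn.conv1d_same(np.zeros((14, 128)), w, b)
        assert out.shape == (14, 128, 16)
        np.testing.assert_allclose(out[..., 0], 0.5)
        np.testing.assert_allclose(out[..., 1:], 0.0)

    def test_delta_kernel_copies_input(self, rng):
        x = rng.standard_normal((14, 128))
        w = np.zeros((1, 8))
        w[0, 0] = 1.0
        out = crnn.conv1d_same(x, w, np.zeros(1))
        np.testing.assert_allclose(out[..., 0], x, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.standard_normal((3, 20))
        w = rng.standard_normal((4, 5))
        b = rng.standard_normal(4)
        out = crnn.conv1d_same(x, w, b)
        k = 5
        xpad = np.pad(x, [(0, 0), (0, k - 1)])
        for c in range(3):
            for v in range(20):
                for f in range(4):
                    expected = b[f] + sum(
                        w[f, i] * xpad[c, v + i] for i in range(k)
                    )
                    assert abs(out[c, v, f] - expected) < 1e-10

    def test_batched_equals_stacked_single(self, rng):
        x = rng.standard_normal((5, 3, 20))
        w = rng.standard_normal((4, 5))
        b = rng.standard_normal(4)
        batch = crnn.conv1d_same(x, w, b)
        for i in range(5):
            np.testing.assert_allclose(batch[i], crnn.conv1d_same(x[i], w, b))


class TestBatchNorm:
    def test_train_mode_standardizes(self, rng):
        x = rng.standard_normal((8, 3, 10, 16)) * 4 + 2
        out, _ = crnn.batchnorm_forward(
            x, np.ones(16), np.zeros(16), mode="train", eps=1e-12
        )
        axes = (0, 1, 2)
        assert np.abs(out.mean(axis=axes)).max() < 1e-7
        assert np.abs(out.var(axis=axes) - 1).max() < 1e-6

    def test_affine_contract(self, rng):
        x = rng.standard_normal((64, 2, 5, 3))
        out, _ = crnn.batchnorm_forward(
            x, np.full(3, 2.0), np.full(3, 3.0), mode="train", eps=1e-12
        )
        axes = (0, 1, 2)
        np.testing.assert_allclose(out.mean(axis=axes), 3.0, atol=1e-7)
        np.testing.assert_allclose(out.std(axis=axes), 2.0, atol=1e-6)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((6, 2, 4, 3))
        gamma = rng.standard_normal(3)
        beta = rng.standard_normal(3)
        eps = 1e-5
        out, _ = crnn.batchnorm_forward(x, gamma, beta, mode="train", eps=eps)
        for q in range(3):
            vals = x[..., q].ravel()
            mean = vals.sum() / vals.size
            var = ((vals - mean) ** 2).sum() / vals.size
            expected = gamma[q] * (vals - mean) / np.sqrt(var + eps) + beta[q]
            np.testing.assert_allclose(out[..., q].ravel(), expected, atol=1e-10)

    def test_eval_mode_uses_running_stats(self, rng):
        x = rng.standard_normal((4, 2, 4, 2))
        running = (np.array([1.0, -1.0]), np.array([4.0, 9.0]))
        out, _ = crnn.batchnorm_forward(
            x, np.ones(2), np.zeros(2), mode="eval", running=running, eps=0.0
        )
        expected = (x - running[0]) / np.sqrt(running[1])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_single_sample_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            crnn.batchnorm_forward(
                rng.standard_normal((1, 2, 4, 2)), np.ones(2), np.zeros(2)
            )


class TestActivations:
    def test_relu_examples(self):
        np.testing.assert_array_equal(
            crnn.activation(np.array([-1.5, 0.0, 2.0]), "relu"),
            np.array([0.0, 0.0, 2.0]),
        )

    def test_sigmoid_at_zero(self):
        assert crnn.activation(np.array([0.0]), "sigmoid")[0] == pytest.approx(0.5)

    def test_tanh_sigmoid_identity(self, rng):
        x = rng.uniform(-5, 5, 100)
        lhs = crnn.activation(x, "tanh")
        rhs = 2 * crnn.activation(2 * x, "sigmoid") - 1
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_relu_idempotent(self, rng):
        x = rng.standard_normal(100)
        once = crnn.activation(x, "relu")
        np.testing.assert_array_equal(crnn.activation(once, "relu"), once)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            crnn.activation(np.zeros(3), "softplus")


class TestMaxPoolSame:
    def test_hand_worked_toy(self):
        out = crnn.maxpool_same(np.array([1.0, 3.0, 2.0]), axis=-1)
        np.testing.assert_array_equal(out, [3.0, 3.0, 2.0])

    def test_non_increasing_nonnegative_is_fixed_point(self):
        x = np.array([5.0, 4.0, 4.0, 1.0, 0.0])
        np.testing.assert_array_equal(crnn.maxpool_same(x, axis=-1), x)

    def test_constant_nonnegative_unchanged(self):
        x = np.full((2, 7), 3.3)
        np.testing.assert_array_equal(crnn.maxpool_same(x, axis=-1), x)

    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 30),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    @settings(derandomize=True, max_examples=50)
    def test_dominates_nonnegative_input(self, x):
        out = crnn.maxpool_same(x, axis=-1)
        assert (out >= x).all()

    def test_length_preserved_on_activation_tensor(self, rng):
        x = np.abs(rng.standard_normal((2, 3, 9, 4)))
        assert crnn.maxpool_same(x, axis=2).shape == x.shape


class TestDropout:
    def test_eval_mode_is_identity(self, rng):
        x = rng.standard_normal((10, 10))
        out, mask = crnn.dropout(x, 0.5, rng, mode="eval")
        assert mask is None
        np.testing.assert_array_equal(out, x)

    def test_p_zero_is_identity(self, rng):
        x = rng.standard_normal((10, 10))
        out, _ = crnn.dropout(x, 0.0, rng, mode="train")
        np.testing.assert_array_equal(out, x)

    def test_zeroed_fraction_binomial(self, rng):
        x = np.ones(100_000)
        out, _ = crnn.dropout(x, 0.5, rng, mode="train")
        frac = (out == 0).mean()
        sigma = np.sqrt(0.25 / x.size)
        assert abs(frac - 0.5) < 3 * sigma
        # survivors rescaled by 1/(1-p)
        assert np.allclose(out[out != 0], 2.0)


class TestLSTM:
    def test_zero_input_zero_weights_unit_forget_bias(self):
        d, u = 6, 3
        W = np.zeros((4 * u, d))
        R = np.zeros((4 * u, u))
        b = np.zeros(4 * u)
        b[u : 2 * u] = 1.0
        h, _ = crnn.lstm_step(np.zeros((1, d)), W, R, b)
        np.testing.assert_array_equal(h, 0)

    def test_output_bounded_by_tanh(self, rng):
        d, u = 8, 4
        W = rng.standard_normal((4 * u, d)) * 3
        R = rng.standard_normal((4 * u, u))
        b = rng.standard_normal(4 * u)
        h, _ = crnn.lstm_step(rng.standard_normal((5, d)) * 10, W, R, b)
        assert (np.abs(h) < 1).all()

    def test_matches_gate_equation_oracle(self, rng):
        # Hand-rolled single-step oracle on a small instance, nonzero state.
        d, u = 4, 2
        W = rng.standard_normal((4 * u, d))
        R = rng.standard_normal((4 * u, u))
        b = rng.standard_normal(4 * u)
        x = rng.standard_normal((3, d))
        h0 = rng.standard_normal((3, u))
        c0 = rng.standard_normal((3, u))
        h, _ = crnn.lstm_step(x, W, R, b, h0=h0, c0=c0)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        for n in range(3):
            z = W @ x[n] + R @ h0[n] + b
            i, f = sig(z[:u]), sig(z[u : 2 * u])
            g, o = np.tanh(z[2 * u : 3 * u]), sig(z[3 * u :])
            c = f * c0[n] + i * g
            np.testing.assert_allclose(h[n], o * np.tanh(c), atol=1e-10)

    def test_wrong_length_rejected(self):
        params = crnn.init_params(crnn.CRNNConfig())
        with pytest.raises(ValueError):
            crnn.lstm_features(np.zeros(100), params)


class TestParameterAccounting:
    def test_replication_counts(self):
        counts = crnn.count_parameters(crnn.CRNNConfig())
        assert counts["conv"] == 144
        assert counts["batchnorm"] == 32
        assert counts["lstm"] == 3_674_240
        assert counts["head"] == 132

    def test_toy_lstm_count(self):
        cfg = crnn.CRNNConfig(
            n_channels=1, segment_len=1, n_filters=1, kernel_size=1, lstm_units=1
        )
        assert crnn.count_parameters(cfg)["lstm"] == 12

    def test_params_match_counts(self):
        cfg = crnn.CRNNConfig()
        params = crnn.init_params(cfg)
        counts = crnn.count_parameters(cfg)
        assert params.conv_w.size + params.conv_b.size == counts["conv"]
        assert params.bn_gamma.size + params.bn_beta.size == counts["batchnorm"]
        assert (
            params.lstm_W.size + params.lstm_R.size + params.lstm_b.size
            == counts["lstm"]
        )
        assert params.head_W.size + params.head_b.size == counts["head"]


def toy_two_class_data(n=64, seed=0):
    """5 Hz vs 40 Hz oscillations + noise; trivially separable."""
    rng = np.random.default_rng(seed)
    t = np.arange(128) / 128
    X = rng.standard_normal((n, 14, 128)).astype(np.float32) * 0.3
    y = np.arange(n) % 2
    for i in range(n):
        f = 5.0 if y[i] == 0 else 40.0
        phases = rng.uniform(0, 2 * np.pi, 14)
        X[i] += np.sin(2 * np.pi * f * t[None, :] + phases[:, None]).astype(
            np.float32
        )
    return X, y


class TestTraining:
    def test_same_seed_identical_first_epoch_loss(self):
        X, y = toy_two_class_data(n=32)
        cfg = dataclasses.replace(crnn.CRNNConfig(), epochs=1, batch_size=16, seed=3)
        _, h1 = crnn.train_crnn(X, y, cfg)
        _, h2 = crnn.train_crnn(X, y, cfg)
        assert h1.epoch_loss[0] == h2.epoch_loss[0]

    def test_loss_decreases_and_features_separate(self):
        X, y = toy_two_class_data(n=64)
        cfg = dataclasses.replace(crnn.CRNNConfig(), epochs=8, batch_size=32, seed=0)
        params, hist = crnn.train_crnn(X, y, cfg)
        assert hist.epoch_loss[-1] < hist.epoch_loss[0]
        feats = crnn.extract_features(X, params, cfg)
        c0, c1 = feats[y == 0].mean(axis=0), feats[y == 1].mean(axis=0)
        between = np.linalg.norm(c0 - c1)
        within = np.mean(
            [
                np.linalg.norm(feats[y == k] - [c0, c1][k], axis=1).mean()
                for k in (0, 1)
            ]
        )
        assert between > within

    def test_extract_features_deterministic_and_finite(self):
        X, y = toy_two_class_data(n=16)
        cfg = dataclasses.replace(crnn.CRNNConfig(), epochs=1, batch_size=8, seed=1)
        params, _ = crnn.train_crnn(X, y, cfg)
        f1 = crnn.extract_features(X, params, cfg)
        f2 = crnn.extract_features(X, params, cfg)
        np.testing.assert_array_equal(f1, f2)
        assert np.isfinite(f1).all()
        assert f1.shape == (16, 32)

    def test_checkpoint_roundtrip(self, tmp_path):
        cfg = crnn.CRNNConfig()
        params = crnn.init_params(cfg)
        path = tmp_path / "model.npz"
        params.save(path, cfg)
        loaded = crnn.CRNNParams.load(path)
        np.testing.assert_array_equal(loaded.lstm_W, params.lstm_W)
        np.testing.assert_array_equal(loaded.bn_var, params.bn_var)
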