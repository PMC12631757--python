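"""SE block, self-attention and classifier forward/backward behaviour."""

import numpy as np
import pytest

import hhtsann as h
from hhtsann.exceptions import DimensionError
from hhtsann.network import SEParams, softmax


class TestSqueeze:
    def test_constant_column_and_ramp(self):
        F = np.column_stack([np.full(4, 7.0), np.arange(1.0, 5.0)])
        np.testing.assert_allclose(h.squeeze(F), [7.0, 2.5])

    def test_matches_independent_mean(self, rng):
        F = rng.standard_normal((50, 8))
        brute = np.array([sum(F[t, c] for t in range(50)) / 50 for c in range(8)])
        np.testing.assert_allclose(h.squeeze(F), brute, atol=1e-12)


class TestExcite:
    def test_zero_weights_give_half(self):
        p = SEParams(W1=np.zeros((2, 4)), W2=np.zeros((4, 2)))
        np.testing.assert_allclose(h.excite(np.ones(4), p), np.full(4, 0.5))

    def test_hand_computed_relu_kill(self):
        # hidden = relu(1*1 + 1*(-1)) = 0 -> s = sigmoid(0) = 0.5
        p = SEParams(W1=np.array([[1.0, 1.0]]), W2=np.array([[1.0], [-1.0]]), r=2)
        np.testing.assert_allclose(h.excite(np.array([1.0, -1.0]), p), [0.5, 0.5])

    def test_open_unit_interval(self, rng):
        p = SEParams.random(6, 2, rng)
        s = h.excite(rng.standard_normal(6) * 100, p)
        assert np.all(s > 0) and np.all(s < 1)

    def test_shape_mismatch(self, rng):
        p = SEParams.random(6, 2, rng)
        with pytest.raises(DimensionError):
            h.excite(np.zeros(5), p)


class TestSeScale:
    def test_limit_gates(self, rng):
        F = rng.standard_normal((10, 4))
        np.testing.assert_array_equal(h.se_scale(F, np.ones(4)), F)
        np.testing.assert_array_equal(h.se_scale(F, np.zeros(4)), np.zeros_like(F))

    def test_contraction_in_frobenius_norm(self, rng):
        # gates in (0,1) can only shrink every entry, hence the whole map
        for _ in range(100):
            F = rng.standard_normal((6, 5))
            p = SEParams.random(5, 1, rng)
            scaled = h.se_scale(F, h.excite(h.squeeze(F), p))
            assert np.all(np.abs(scaled) <= np.abs(F))
            assert np.linalg.norm(scaled) <= np.linalg.norm(F)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            h.se_scale(np.zeros((3, 4)), np.zeros(3))


class TestSelfAttention:
    def test_single_timestep_degenerates_to_value_projection(self, rng):
        p = h.AttentionParams.random(5, 3, rng)
        F = rng.standard_normal((1, 5))
        out, w = h.self_attention(F, p, return_weights=True)
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(out, F @ p.Wv)

    def test_zero_queries_give_uniform_attention(self, rng):
        p = h.AttentionParams(
            Wq=np.zeros((5, 3)), Wk=np.zeros((5, 3)), Wv=rng.standard_normal((5, 3))
        )
        F = rng.standard_normal((7, 5))
        out = h.self_attention(F, p)
        mean_row = (F @ p.Wv).mean(axis=0)
        np.testing.assert_allclose(out, np.tile(mean_row, (7, 1)), atol=1e-12)

    def test_rows_are_stochastic_for_random_draws(self, rng):
        for _ in range(100):
            p = h.AttentionParams.random(4, 6, rng)
            F = rng.standard_normal((9, 4))
            _, w = h.self_attention(F, p, return_weights=True)
            np.testing.assert_allclose(w.sum(axis=1), np.ones(9), atol=1e-6)
            assert np.all(w >= 0)


class TestClassifier:
    @pytest.fixture()
    def model_and_batch(self, rng):
        cfg = h.NetworkConfig(attn_dim=4, reduction=2, time_pool=1)
        model = h.HhtSannClassifier(6, cfg, rng=5)
        X = rng.standard_normal((5, 8, 6))
        return model, X

    def test_probabilities_normalised_and_deterministic(self, model_and_batch):
        model, X = model_and_batch
        out1 = model.forward_features(X)
        out2 = model.forward_features(X)
        np.testing.assert_allclose(out1.probabilities.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(out1.logits, out2.logits)

    def test_identical_epochs_identical_rows(self, model_and_batch, rng):
        model, _ = model_and_batch
        row = rng.standard_normal((1, 8, 6))
        out = model.forward_features(np.repeat(row, 4, axis=0))
        for k in range(1, 4):
            np.testing.assert_array_equal(out.probabilities[k], out.probabilities[0])

    def test_zero_head_gives_coin_flip(self, model_and_batch):
        model, X = model_and_batch
        model.params["Wh"][:] = 0.0
        model.params["bh"][:] = 0.0
        np.testing.assert_allclose(
            model.forward_features(X).probabilities, 0.5, atol=1e-12
        )

    def test_gradients_match_finite_differences(self, model_and_batch, rng):
        model, X = model_and_batch
        y = rng.integers(0, 2, len(X))
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for name in ("W1", "W2", "Wq", "Wk", "Wv", "Wh", "bh"):
            g = grads[name]
            flat = rng.choice(g.size, size=min(5, g.size), replace=False)
            for j in flat:
                idx = np.unravel_index(j, g.shape)
                orig = model.params[name][idx]
                model.params[name][idx] = orig + eps
                lp, _ = model.loss_and_grads(X, y)
                model.params[name][idx] = orig - eps
                lm, _ = model.loss_and_grads(X, y)
                model.params[name][idx] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(g[idx]), 1e-8)
                assert abs(num - g[idx]) / denom < 1e-2
            assert np.any(g != 0), f"gradient of {name} vanished"

    def test_checkpoint_round_trip(self, model_and_batch, tmp_path):
        model, X = model_and_batch
        model.fit_standardizer(X)
        path = tmp_path / "m.ckpt.npz"
        model.save(path)
        back = h.HhtSannClassifier.load(path)
        np.testing.assert_array_equal(
            back.forward_features(X).logits, model.forward_features(X).logits
        )
        assert back.cfg == model.cfg

    def test_feature_shape_validated(self, model_and_batch):
        model, _ = model_and_batch
        with pytest.raises(DimensionError):
            model.forward_features(np.zeros((2, 8, 7)))


class TestFeatureTensor:
    def test_layout_and_pooling(self, tiny_epochs, tiny_net_cfg):
        X, index = h.features_for_epochset(tiny_epochs, tiny_net_cfg)
        n_ch = tiny_epochs.n_channels
        expected_cols = n_ch * (1 + 2 * tiny_net_cfg.max_imfs)
        assert X.shape == (
            tiny_epochs.n_epochs,
            tiny_epochs.window_samples // tiny_net_cfg.time_pool,
            expected_cols,
        )
        kinds = [k.kind for k in index]
        assert kinds[:n_ch] == ["raw"] * n_ch
        assert set(kinds[n_ch:]) == {"amplitude", "frequency"}

    def test_hht_only_mode_drops_raw_planes(self, tiny_epochs):
        cfg = h.NetworkConfig(max_imfs=2, include_raw=False, time_pool=16)
        X, index = h.features_for_epochset(tiny_epochs, cfg)
        assert all(k.kind != "raw" for k in index)
        assert X.shape[-1] == tiny_epochs.n_channels * 4

    def test_softmax_rows_sum_to_one(self, rng):
        s = softmax(rng.standard_normal((20, 7)) * 30)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-9)
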