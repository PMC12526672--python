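"""FT-Transformer: tokenizer, encoder, training behaviour, persistence."""

import numpy as np
import pytest

from asft.autodiff import cross_entropy
from asft.fttransformer import (FTTConfig, FTTransformer, FittedModel, fit,
                                predict)
from asft.studies import separable_blobs

TINY = dict(d_embed=16, n_layers=1, n_heads=2, ffn_hidden=8, dropout=0.0)


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            FTTConfig(d_embed=30, n_heads=8)

    def test_negative_layers_rejected(self):
        with pytest.raises(ValueError):
            FTTConfig(n_layers=-1)


class TestTokenizer:
    def test_token_matrix_shape_192_64(self):
        model = FTTransformer(192, FTTConfig())
        tokens = model.tokenizer(np.zeros((2, 192), dtype=np.float32))
        assert tokens.shape == (2, 193, 64)

    def test_zero_input_gives_bias_tokens(self):
        model = FTTransformer(5, FTTConfig(**TINY))
        tokens = model.tokenizer(np.zeros((1, 5), dtype=np.float32))
        np.testing.assert_array_equal(tokens.data[0, 1:], model.tokenizer.b.data)
        np.testing.assert_array_equal(tokens.data[0, 0],
                                      model.tokenizer.cls.data[0, 0])

    def test_tokenizer_is_affine(self, rng):
        model = FTTransformer(6, FTTConfig(**TINY))
        x = rng.standard_normal((3, 6)).astype(np.float32)
        y = rng.standard_normal((3, 6)).astype(np.float32)
        t = model.tokenizer
        left = t(x + y).data - t(y).data
        right = t(x).data - t(np.zeros_like(x)).data
        np.testing.assert_allclose(left, right, atol=1e-5)

    def test_width_mismatch_rejected(self):
        model = FTTransformer(4, FTTConfig(**TINY))
        with pytest.raises(ValueError):
            model.tokenizer(np.zeros((1, 5), dtype=np.float32))

    def test_non_finite_rejected(self):
        model = FTTransformer(2, FTTConfig(**TINY))
        with pytest.raises(ValueError):
            model.tokenizer(np.array([[np.nan, 0.0]], dtype=np.float32))


class TestForward:
    def test_eval_mode_bit_identical(self, rng):
        model = FTTransformer(8, FTTConfig(**TINY))
        x = rng.standard_normal((4, 8)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x).data,
                                      model.forward(x).data)

    def test_feature_permutation_invariance(self, rng):
        # permuting feature tokens together with their tokenizer parameters
        # must leave the logits unchanged (self-attention has no positions)
        model = FTTransformer(7, FTTConfig(**TINY, seed=5))
        x = rng.standard_normal((3, 7)).astype(np.float32)
        base = model.forward(x).data.copy()
        perm = rng.permutation(7)
        model.tokenizer.W.data = model.tokenizer.W.data[perm]
        model.tokenizer.b.data = model.tokenizer.b.data[perm]
        permuted = model.forward(x[:, perm]).data
        np.testing.assert_allclose(permuted, base, atol=1e-4)

    def test_zero_layer_degenerate_config(self, rng):
        model = FTTransformer(4, FTTConfig(**{**TINY, "n_layers": 0}))
        out = model.forward(rng.standard_normal((2, 4)).astype(np.float32))
        assert out.shape == (2, 2)
        assert np.isfinite(out.data).all()

    def test_first_layer_has_no_leading_attention_norm(self):
        model = FTTransformer(4, FTTConfig(**{**TINY, "n_layers": 2}))
        assert model.layers[0].norm_attn is None
        assert model.layers[1].norm_attn is not None


class TestFit:
    def test_separable_blobs_high_train_accuracy(self):
        X, y = separable_blobs(400, seed=0)
        cfg = FTTConfig(**TINY, epochs=15, batch_size=32, seed=0)
        fitted = fit(X, y, cfg)
        assert (fitted.predict(X) == y).mean() >= 0.99
        assert fitted.loss_history[-1] < fitted.loss_history[0]

    def test_seeded_reproducibility(self):
        X, y = separable_blobs(200, seed=1)
        cfg = FTTConfig(**TINY, epochs=3, batch_size=32, seed=9)
        f1, f2 = fit(X, y, cfg), fit(X, y, cfg)
        assert f1.loss_history == f2.loss_history
        np.testing.assert_array_equal(f1.predict_logits(X),
                                      f2.predict_logits(X))

    def test_label_shuffle_near_chance_on_holdout(self):
        X, y = separable_blobs(400, seed=2)
        rng = np.random.default_rng(3)
        y_shuf = rng.permutation(y)
        cfg = FTTConfig(**TINY, epochs=10, batch_size=32, seed=0)
        fitted = fit(X[:300], y_shuf[:300], cfg)
        acc = (fitted.predict(X[300:]) == y_shuf[300:]).mean()
        assert 0.3 <= acc <= 0.7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit(np.zeros((10, 2)), np.zeros(10, dtype=int),
                FTTConfig(**TINY, epochs=1))

    def test_constant_feature_handled(self):
        X, y = separable_blobs(100, seed=4)
        X = np.c_[X, np.full(len(X), 3.0)]  # zero-variance column
        fitted = fit(X, y, FTTConfig(**TINY, epochs=2, seed=0))
        assert np.isfinite(fitted.loss_history[-1])


@pytest.fixture(scope="module")
def fitted():
    X, y = separable_blobs(400, seed=0)
    return fit(X, y, FTTConfig(**TINY, epochs=15, batch_size=32, seed=0)), X, y


class TestPredict:

    def test_probabilities_sum_to_one(self, fitted):
        model, X, _ = fitted
        proba, labels = predict(model, X[:50])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, proba.argmax(axis=1))

    def test_holdout_blobs_accuracy(self, fitted):
        model, _, _ = fitted
        Xh, yh = separable_blobs(300, seed=11)
        assert (model.predict(Xh) == yh).mean() >= 0.98

    def test_width_mismatch(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError):
            model.predict(np.zeros((3, 5)))

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, X, _ = fitted
        path = model.save(tmp_path / "ckpt.npz")
        back = FittedModel.load(path)
        np.testing.assert_array_equal(back.predict_logits(X[:20]),
                                      model.predict_logits(X[:20]))
        assert back.cfg == model.cfg


class TestCategoricalTokenizer:
    def test_lookup_tokens_and_shapes(self, rng):
        from asft.fttransformer import CategoricalTokenizer
        tok = CategoricalTokenizer(rng, cardinalities=[3, 5], d=4,
                                   dtype=np.float32)
        x = np.array([[0, 4], [2, 1]])
        tokens = tok(x)
        assert tokens.shape == (2, 2, 4)
        np.testing.assert_allclose(
            tokens.data[0, 1], tok.tables[1].data[4] + tok.b.data[1],
            atol=1e-6)

    def test_width_mismatch(self, rng):
        from asft.fttransformer import CategoricalTokenizer
        tok = CategoricalTokenizer(rng, cardinalities=[2], d=4,
                                   dtype=np.float32)
        with pytest.raises(ValueError):
            tok(np.zeros((1, 2), dtype=int))
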