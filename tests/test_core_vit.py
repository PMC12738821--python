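"""Encoder building blocks against hand-computed and independent oracles."""

import math

import numpy as np
import pytest

import leafvit as lv
from leafvit.core_vit import extract_patches
from leafvit.layers import layer_norm, softmax


def _mk_attn_params(d, h, rng=None, identity_out=True):
    dk = d // h
    rng = rng or np.random.default_rng(0)
    p = {
        "Wq": rng.normal(0, 0.3, (h, d, dk)),
        "Wk": rng.normal(0, 0.3, (h, d, dk)),
        "Wv": rng.normal(0, 0.3, (h, d, dk)),
        "Wo": np.eye(d) if identity_out else rng.normal(0, 0.3, (d, d)),
    }
    return p


class TestEmbedPatches:
    def test_sequence_length(self):
        cfg = lv.ModelConfig(image_size=64, patch_size=8, embed_dim=16, num_heads=2)
        img = np.zeros((64, 64, 3))
        E = np.zeros((8 * 8 * 3, 16))
        Epos = np.zeros((65, 16))
        tokens = lv.embed_patches(img, cfg, E, Epos, np.zeros(16))
        assert tokens.shape == (65, 16)

    def test_zero_image_returns_position_encoding(self, rng):
        cfg = lv.ModelConfig(image_size=16, patch_size=4, embed_dim=8, num_heads=2)
        E = rng.normal(size=(48, 8))
        Epos = rng.normal(size=(17, 8))
        tokens = lv.embed_patches(np.zeros((16, 16, 3)), cfg, E, Epos, np.zeros(8))
        np.testing.assert_array_equal(tokens, Epos)

    def test_manual_raster_order(self):
        # 2x2 single-channel image, p=1, d=1, identity projection:
        # tokens must be (CLS=0, 1, 2, 3, 4) in raster order
        cfg = lv.ModelConfig(
            image_size=2, patch_size=1, channels=1, embed_dim=1, num_heads=1
        )
        img = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        tokens = lv.embed_patches(
            img, cfg, np.ones((1, 1)), np.zeros((5, 1)), np.zeros(1)
        )
        np.testing.assert_allclose(tokens[:, 0], [0, 1, 2, 3, 4])

    def test_shape_errors(self):
        cfg = lv.ModelConfig(image_size=16, patch_size=4, embed_dim=8, num_heads=2)
        with pytest.raises(ValueError):
            lv.embed_patches(
                np.zeros((16, 16, 3)), cfg, np.zeros((10, 8)), np.zeros((17, 8)),
                np.zeros(8),
            )
        with pytest.raises(ValueError):
            extract_patches(np.zeros((15, 16, 3)), 4)


class TestMultiHeadAttention:
    def test_single_token_returns_value(self, rng):
        cfg = lv.ModelConfig(image_size=8, patch_size=8, embed_dim=4, num_heads=1)
        params = _mk_attn_params(4, 1, rng)
        x = rng.normal(size=(1, 4))
        out = lv.multi_head_attention(x, params, cfg)
        np.testing.assert_allclose(out, x @ params["Wv"][0], atol=1e-12)

    def test_identical_keys_give_value_mean(self, rng):
        cfg = lv.ModelConfig(image_size=16, patch_size=8, embed_dim=4, num_heads=1)
        params = _mk_attn_params(4, 1, rng)
        params["Wk"] = np.zeros_like(params["Wk"])  # all keys identical (zero)
        x = rng.normal(size=(5, 4))
        out = lv.multi_head_attention(x, params, cfg)
        V = x @ params["Wv"][0]
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (5, 1)), atol=1e-12)

    def test_two_token_scalar_softmax_oracle(self):
        # h=1, dk=1: attention weights are a scalar softmax computed by hand
        cfg = lv.ModelConfig(image_size=8, patch_size=8, embed_dim=1, num_heads=1)
        Wq = np.array([[[2.0]]])
        Wk = np.array([[[1.0]]])
        Wv = np.array([[[-1.0]]])
        params = {"Wq": Wq, "Wk": Wk, "Wv": Wv, "Wo": np.eye(1)}
        x = np.array([[1.0], [3.0]])
        q, k, v = 2 * x[:, 0], x[:, 0], -x[:, 0]
        expected = []
        for i in range(2):
            s = np.array([q[i] * k[0], q[i] * k[1]])  # dk = 1 -> no scaling change
            w = np.exp(s - s.max())
            w /= w.sum()
            expected.append(w @ v)
        out = lv.multi_head_attention(x, params, cfg)
        np.testing.assert_allclose(out[:, 0], expected, rtol=1e-12)

    def test_nonfinite_input_rejected(self, tiny_cfg):
        params = _mk_attn_params(8, 2)
        x = np.full((3, 8), np.nan)
        with pytest.raises(FloatingPointError):
            lv.multi_head_attention(x, params, tiny_cfg)


class TestMlpBlock:
    def test_zero_input_zero_bias(self):
        params = {
            "W1": np.ones((4, 16)), "b1": np.zeros(16),
            "W2": np.ones((16, 4)), "b2": np.zeros(4),
        }
        out = lv.mlp_block(np.zeros((3, 4)), params)
        np.testing.assert_array_equal(out, 0)

    def test_zero_w1_constant_rows(self, rng):
        params = {
            "W1": np.zeros((4, 16)), "b1": rng.normal(size=16),
            "W2": rng.normal(size=(16, 4)), "b2": rng.normal(size=4),
        }
        x = rng.normal(size=(5, 4))
        out = lv.mlp_block(x, params)
        assert np.allclose(out, out[0])

    def test_gelu_one_matches_stdlib_erf(self):
        # d=1 path isolating a single GELU(1) evaluation; oracle uses math.erf
        params = {
            "W1": np.array([[1.0, 0, 0, 0]]), "b1": np.zeros(4),
            "W2": np.array([[1.0], [0], [0], [0]]), "b2": np.zeros(1),
        }
        out = lv.mlp_block(np.array([[1.0]]), params)
        expected = 0.5 * 1.0 * (1.0 + math.erf(1.0 / math.sqrt(2.0)))
        np.testing.assert_allclose(out[0, 0], expected, rtol=1e-14)


def _ref_layernorm(x):
    mu = x.mean(axis=-1, keepdims=True)
    sd = np.sqrt(x.var(axis=-1, keepdims=True) + 1e-5)
    return (x - mu) / sd


class TestEncoderLayer:
    def _zero_params(self, d=8, h=2):
        dk = d // h
        attn = {
            "Wq": np.zeros((h, d, dk)), "Wk": np.zeros((h, d, dk)),
            "Wv": np.zeros((h, d, dk)), "Wo": np.zeros((d, d)),
        }
        mlp = {
            "W1": np.zeros((d, 4 * d)), "b1": np.zeros(4 * d),
            "W2": np.zeros((4 * d, d)), "b2": np.zeros(d),
        }
        return attn, mlp

    def test_zero_sublayers_double_layernorm(self, tiny_cfg, rng):
        attn, mlp = self._zero_params()
        x = rng.normal(size=(5, 8))
        out = lv.encoder_layer(x, attn, mlp, tiny_cfg)
        np.testing.assert_allclose(out, _ref_layernorm(_ref_layernorm(x)), atol=1e-12)

    def test_drop_path_one_drops_both_branches(self, rng):
        cfg = lv.ModelConfig(
            image_size=16, patch_size=4, embed_dim=8, num_heads=2,
            drop_path_rate=1.0,
        )
        attn = _mk_attn_params(8, 2, rng)
        mlp = {
            "W1": rng.normal(size=(8, 32)), "b1": rng.normal(size=32),
            "W2": rng.normal(size=(32, 8)), "b2": rng.normal(size=8),
        }
        x = rng.normal(size=(5, 8))
        out = lv.encoder_layer(
            x, attn, mlp, cfg, training=True, rng=np.random.default_rng(1)
        )
        np.testing.assert_allclose(out, _ref_layernorm(_ref_layernorm(x)), atol=1e-12)

    def test_three_token_sequential_oracle(self, tiny_cfg, rng):
        # independent straight-line recomputation of the post-norm wiring
        d, h = 8, 2
        attn = _mk_attn_params(d, h, rng, identity_out=False)
        mlp = {
            "W1": rng.normal(0, 0.3, (d, 4 * d)), "b1": rng.normal(size=4 * d),
            "W2": rng.normal(0, 0.3, (4 * d, d)), "b2": rng.normal(size=d),
        }
        x = rng.normal(size=(3, d))

        heads = []
        for hh in range(h):
            Q = x @ attn["Wq"][hh]
            K = x @ attn["Wk"][hh]
            V = x @ attn["Wv"][hh]
            S = Q @ K.T / np.sqrt(d // h)
            W = np.exp(S - S.max(axis=1, keepdims=True))
            W = W / W.sum(axis=1, keepdims=True)
            heads.append(W @ V)
        a = np.concatenate(heads, axis=1) @ attn["Wo"]
        x1 = _ref_layernorm(x + a)
        z = x1 @ mlp["W1"] + mlp["b1"]
        g = 0.5 * z * (1 + np.vectorize(math.erf)(z / math.sqrt(2)))
        m = g @ mlp["W2"] + mlp["b2"]
        expected = _ref_layernorm(x1 + m)

        out = lv.encoder_layer(x, attn, mlp, tiny_cfg)
        np.testing.assert_allclose(out, expected, rtol=1e-8, atol=1e-10)


class TestClassifyHead:
    def test_zero_weights_uniform(self, rng):
        x = rng.normal(size=(5, 8))
        probs = lv.classify_head(x, np.zeros((8, 4)))
        np.testing.assert_allclose(probs, 0.25)

    def test_probability_simplex(self, rng):
        probs = lv.classify_head(rng.normal(size=(5, 8)), rng.normal(size=(8, 4)))
        assert np.isclose(probs.sum(), 1.0)
        assert np.all((probs > 0) & (probs < 1))

    def test_two_dim_manual(self):
        x = np.zeros((3, 2))
        x[0] = [1.0, 3.0]
        W = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 1.0, 2.0, 0.0]])
        u = (x[0] - x[0].mean()) / np.sqrt(x[0].var() + 1e-5)
        logits = u @ W
        e = np.exp(logits - logits.max())
        np.testing.assert_allclose(lv.classify_head(x, W), e / e.sum(), rtol=1e-12)


class TestProfileAndCheckpoint:
    def test_tiny_preset_shape_ledger(self):
        cfg = lv.ModelConfig(
            image_size=32, patch_size=8, embed_dim=32, num_heads=4, num_layers=2
        )
        d, N, hidden = 32, 16, 128
        expected = (8 * 8 * 3) * d + d + (N + 1) * d  # embedding
        per_layer = (
            3 * d * d  # per-head q/k/v stacks: h * d * dk = d*d each
            + d * d  # output projection
            + 2 * d + 2 * d  # two LayerNorms
            + d * hidden + hidden + hidden * d + d  # MLP
        )
        expected += 2 * per_layer
        expected += 2 * d + d * 4  # head LayerNorm + linear head
        assert lv.profile_model(cfg)["param_count"] == expected

    def test_flops_scale_with_layers(self):
        f1 = lv.profile_model(lv.TEST_PRESET(num_layers=1))["flop_estimate"]
        f6 = lv.profile_model(lv.TEST_PRESET(num_layers=6))["flop_estimate"]
        embed = f6 - 6 * (f6 - f1) // 5  # non-layer share stays constant
        assert f6 > f1 > 0 and embed >= 0

    def test_checkpoint_roundtrip(self, tmp_path, tiny_cfg, rng):
        params = lv.init_params(tiny_cfg, rng)
        path = str(tmp_path / "model.zip")
        lv.save_checkpoint(path, tiny_cfg, params, meta={"note": "x"})
        cfg2, params2, meta = lv.load_checkpoint(path)
        assert cfg2 == tiny_cfg and meta == {"note": "x"}
        for k in params:
            np.testing.assert_array_equal(params[k], params2[k])


class TestModelInvariants:
    def test_inference_deterministic(self, tiny_cfg, rng):
        model = lv.ViTClassifier(tiny_cfg, rng=np.random.default_rng(3))
        X = rng.random((2, 16, 16, 3))
        a = model.forward(X)
        b = model.forward(X)
        np.testing.assert_array_equal(a, b)

    def test_patch_permutation_invariance_of_cls_readout(self, rng):
        # permuting patch tokens together with their position encodings must
        # leave the classification unchanged (attention has no innate order)
        cfg = lv.ModelConfig(
            image_size=16, patch_size=4, embed_dim=8, num_heads=2, num_layers=2,
            drop_path_rate=0.0,
        )
        attn = _mk_attn_params(8, 2, rng, identity_out=False)
        mlp = {
            "W1": rng.normal(0, 0.3, (8, 32)), "b1": rng.normal(size=32),
            "W2": rng.normal(0, 0.3, (32, 8)), "b2": rng.normal(size=8),
        }
        W_head = rng.normal(size=(8, 4))
        x = rng.normal(size=(17, 8))

        def run(tokens):
            h = tokens
            for _ in range(2):
                h = lv.encoder_layer(h, attn, mlp, cfg)
            return lv.classify_head(h, W_head)

        perm = np.concatenate([[0], 1 + rng.permutation(16)])
        np.testing.assert_allclose(run(x), run(x[perm]), rtol=1e-10)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            lv.ModelConfig(image_size=65, patch_size=8, embed_dim=8, num_heads=2)
        with pytest.raises(ValueError):
            lv.ModelConfig(image_size=64, patch_size=8, embed_dim=9, num_heads=2)
        with pytest.raises(ValueError):
            lv.ModelConfig.from_dict({"image_size": 64, "bogus_key": 1})

    def test_yaml_roundtrip(self, tmp_path):
        cfg = lv.TEST_PRESET(attention_mode="routed")
        path = str(tmp_path / "cfg.yaml")
        cfg.to_yaml(path)
        assert lv.ModelConfig.from_yaml(path) == cfg
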