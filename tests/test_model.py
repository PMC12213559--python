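"""Architecture contracts: shapes, constructed-weight identities, loop-oracle
agreement, gradient flow, parameter counting and checkpointing."""

import numpy as np
import pytest

from dscnet import (
    ModelConfig, ParameterStore, classify, cot_attention, count_parameters,
    dafm, depthwise_separable_conv, embed, forward, load_checkpoint, predict,
    model_summary, save_checkpoint, stage2_round,
)
from dscnet.autodiff import Tensor
from dscnet.model import _lift_params, forward_core

from oracles import classify_loop, conv1d_loop, cot_loop, dafm_loop, dsc_loop


def fmap(rng, c, t):
    return rng.standard_normal((c, 1, t))


# ---------------------------------------------------------------------------
# Stage 1: hybrid representation
# ---------------------------------------------------------------------------

class TestEmbed:
    def test_shape_contract(self, small_cfg, small_store, rng):
        out = embed(fmap(rng, 4, 32), small_cfg, small_store)
        assert out.shape == (16, 1, 32)  # 2 x embed_width, time preserved

    def test_zero_input_zero_output(self, small_cfg, small_store):
        out = embed(np.zeros((4, 1, 32)), small_cfg, small_store)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_constructed_weights_expose_skip_and_projection(self, rng):
        cfg = ModelConfig(in_channels=4, embed_width=4, stage2_width=8,
                          classifier_hidden=8)
        store = ParameterStore.initialize(cfg, seed=0, dtype=np.float64)
        for name in ("embed.conv1", "embed.conv2", "embed.conv3"):
            store.params[f"{name}.w"][:] = 0.0
        eye = np.eye(4)[:, :, None]
        store.params["embed.skip.w"][:] = eye
        store.params["embed.proj.w"][:] = eye
        x = fmap(rng, 4, 16)
        out = embed(x, cfg, store)
        # main path is dead, so both hybrid halves reduce to the input
        np.testing.assert_allclose(out[:4], x, atol=1e-12)
        np.testing.assert_allclose(out[4:], x, atol=1e-12)

    def test_channel_mismatch_rejected(self, small_cfg, small_store, rng):
        with pytest.raises((ValueError, KeyError)):
            forward(fmap(rng, 5, 32), small_cfg, small_store)


# ---------------------------------------------------------------------------
# Stage 2 operators vs explicit-loop oracles
# ---------------------------------------------------------------------------

class TestDepthwiseSeparable:
    def test_delta_kernel_identity(self):
        cfg = ModelConfig(in_channels=4, embed_width=2, stage2_width=4,
                          cot_groups=2, classifier_hidden=8)
        store = ParameterStore.initialize(cfg, seed=0, dtype=np.float64)
        store.params["round0.dw.w"][:] = np.array([0.0, 1.0, 0.0])
        store.params["round0.dw.b"][:] = 0.0
        store.params["round0.pw.w"][:] = np.eye(4)[:, :, None]
        store.params["round0.pw.b"][:] = 0.0
        x = np.random.default_rng(0).standard_normal((4, 1, 12))
        np.testing.assert_allclose(
            depthwise_separable_conv(x, cfg, store), x, atol=1e-12)

    def test_loop_oracle_agreement(self, small_cfg, small_store, rng):
        for _ in range(20):
            x = fmap(rng, small_cfg.hybrid_channels, 8)
            got = depthwise_separable_conv(x, small_cfg, small_store)[:, 0, :]
            ref = dsc_loop(x[:, 0, :], small_store, "round0")
            assert np.abs(got - ref).max() < 1e-5

    def test_shape_contract(self, small_cfg, small_store, rng):
        out = depthwise_separable_conv(fmap(rng, 16, 64), small_cfg, small_store)
        assert out.shape == (16, 1, 64)  # stage2_width, time preserved


class TestDAFM:
    def test_zero_gating(self, small_cfg, rng):
        # modulation multiplies by the input, so x = 0 gives 0 for any weights
        for seed in range(10):
            store = ParameterStore.initialize(small_cfg, seed=seed)
            for k in store.params:
                if "dafm" in k:
                    store.params[k] = rng.standard_normal(store.params[k].shape)
            out = dafm(np.zeros((16, 1, 16)), small_cfg, store)
            np.testing.assert_array_equal(out, 0.0)

    def test_loop_oracle_agreement(self, small_cfg, small_store, rng):
        for _ in range(20):
            x = fmap(rng, 16, 8)
            got = dafm(x, small_cfg, small_store)[:, 0, :]
            ref = dafm_loop(x[:, 0, :], small_cfg, small_store, "round0.dafm")
            assert np.abs(got - ref).max() < 1e-5

    def test_odd_length_loop_oracle(self, small_cfg, small_store, rng):
        # T=9: coarse branch pools to 4, up-samples to 8, edge-pads to 9
        x = fmap(rng, 16, 9)
        got = dafm(x, small_cfg, small_store)[:, 0, :]
        ref = dafm_loop(x[:, 0, :], small_cfg, small_store, "round0.dafm")
        assert np.abs(got - ref).max() < 1e-5

    def test_four_level_variant_preserves_shape(self, rng):
        cfg = ModelConfig(in_channels=4, embed_width=4, stage2_width=8,
                          n_levels=4, cot_groups=2, classifier_hidden=8)
        store = ParameterStore.initialize(cfg, seed=1, dtype=np.float64)
        x = fmap(rng, 8, 16)
        out = dafm(x, cfg, store)
        assert out.shape == (8, 1, 16)
        ref = dafm_loop(x[:, 0, :], cfg, store, "round0.dafm")
        assert np.abs(out[:, 0, :] - ref).max() < 1e-5

    def test_indivisible_channels_rejected(self, small_cfg, small_store, rng):
        with pytest.raises(ValueError):
            dafm(fmap(rng, 15, 16), small_cfg, small_store)

    def test_sign_pattern_matches_independent_gate(self, small_cfg, small_store, rng):
        x = fmap(rng, 16, 8)
        out = dafm(x, small_cfg, small_store)[:, 0, :]
        ref = dafm_loop(x[:, 0, :], small_cfg, small_store, "round0.dafm")
        np.testing.assert_array_equal(np.sign(np.round(out, 10)),
                                      np.sign(np.round(ref, 10)))


class TestCoT:
    def test_zero_propagation(self, small_cfg, small_store):
        out = cot_attention(np.zeros((16, 1, 8)), small_cfg, small_store)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_loop_oracle_agreement(self, small_cfg, small_store, rng):
        for _ in range(20):
            x = fmap(rng, 16, 8)
            got = cot_attention(x, small_cfg, small_store)[:, 0, :]
            ref = cot_loop(x[:, 0, :], small_cfg, small_store, "round0.cot")
            assert np.abs(got - ref).max() < 1e-5

    def test_shape_contract(self, small_cfg, small_store, rng):
        out = cot_attention(fmap(rng, 16, 64), small_cfg, small_store)
        assert out.shape == (16, 1, 64)


class TestStage2Round:
    def test_pooling_arithmetic(self, small_cfg, small_store, rng):
        out = stage2_round(fmap(rng, 16, 64), small_cfg, small_store)
        assert out.shape == (16, 1, 32)

    def test_zeroed_dafm_leaves_cot_branch(self, small_cfg, small_store, rng):
        store = small_store.copy()
        store.params["round0.dafm.fuse.w"][:] = 0.0
        store.params["round0.dafm.fuse.b"][:] = 0.0
        x = fmap(rng, 16, 16)
        got = stage2_round(x, small_cfg, store)[:, 0, :]
        h = depthwise_separable_conv(x, small_cfg, store)
        cot = cot_attention(h, small_cfg, store)[:, 0, :]
        ref = np.maximum(cot[:, 0::2], cot[:, 1::2])
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_too_short_time_axis_rejected(self, small_cfg, small_store, rng):
        with pytest.raises(ValueError):
            stage2_round(fmap(rng, 16, 1), small_cfg, small_store)


class TestClassifier:
    def test_gap_of_constant(self, small_cfg, small_store):
        x = np.full((16, 1, 10), 2.5)
        got = classify(x, small_cfg, small_store)
        ref = classify_loop(x[:, 0, :], small_store)
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_bias_only_final_layer(self, small_cfg, rng):
        store = ParameterStore.initialize(small_cfg, seed=0, dtype=np.float64)
        store.params["cls.fc2.w"][:] = 0.0
        store.params["cls.fc2.b"][:] = [0.3, -0.7]
        for _ in range(3):
            got = classify(fmap(rng, 16, 10), small_cfg, store)
            np.testing.assert_allclose(got, [0.3, -0.7], atol=1e-12)

    def test_linear_algebra_oracle(self, small_cfg, small_store, rng):
        for _ in range(20):
            x = fmap(rng, 16, 12)
            got = classify(x, small_cfg, small_store)
            ref = classify_loop(x[:, 0, :], small_store)
            assert np.abs(got - ref).max() < 1e-5


# ---------------------------------------------------------------------------
# Full forward pass
# ---------------------------------------------------------------------------

class TestForward:
    def test_default_config_shape_and_finiteness(self, rng):
        cfg = ModelConfig(in_channels=32)
        store = ParameterStore.initialize(cfg, seed=0)
        scores = forward(rng.standard_normal((32, 1, 256)), cfg, store)
        assert scores.shape == (2,)
        assert np.all(np.isfinite(scores))

    def test_determinism(self, small_cfg, small_store, rng):
        x = fmap(rng, 4, 32)
        np.testing.assert_array_equal(forward(x, small_cfg, small_store),
                                      forward(x, small_cfg, small_store))

    def test_equals_composition_of_blocks(self, small_cfg, small_store, rng):
        x = fmap(rng, 4, 32)
        h = embed(x, small_cfg, small_store)
        h = stage2_round(h, small_cfg, small_store, round_index=0)
        h = stage2_round(h, small_cfg, small_store, round_index=1)
        composed = classify(h, small_cfg, small_store)
        np.testing.assert_array_equal(forward(x, small_cfg, small_store), composed)

    def test_time_axis_too_short_rejected(self, small_cfg, small_store, rng):
        with pytest.raises(ValueError):
            forward(fmap(rng, 4, 3), small_cfg, small_store)

    def test_predict_argmax_and_tie_break(self, small_cfg):
        store = ParameterStore.initialize(small_cfg, seed=0, dtype=np.float64)
        store.params["cls.fc2.w"][:] = 0.0
        store.params["cls.fc2.b"][:] = 0.0  # tied scores -> lower class wins
        x = np.random.default_rng(3).standard_normal((3, 4, 1, 32))
        np.testing.assert_array_equal(predict(x, small_cfg, store), [0, 0, 0])


# ---------------------------------------------------------------------------
# Parameter counting, ablation lattice, gradients, checkpoints
# ---------------------------------------------------------------------------

def test_count_parameters_closed_form():
    cfg = ModelConfig(in_channels=4, embed_width=8, stage2_width=16,
                      cot_groups=4, classifier_hidden=16)
    # independent shape walk, written out longhand
    embed_n = (8 * 4 * 3 + 8) + (8 * 8 * 3 + 8) * 2 + 2 * 16 * 3 // 2 + (8 * 4 + 8) * 2
    embed_n = (8 * 4 * 3 + 8) + 16 + (8 * 8 * 3 + 8) + 16 + (8 * 8 * 3 + 8) + 16 \
        + (8 * 4 + 8) + (8 * 4 + 8)
    per_round = (16 * 3 + 16) + (16 * 16 + 16) \
        + ((8 * 3 + 8) + (8 * 3 + 8) + (16 * 16 + 16)) \
        + ((16 * 4 * 3 + 16) + (8 * 32 + 8) + (48 * 8 + 48) + (16 * 16 + 16))
    head = (16 * 16 + 16) + (2 * 16 + 2)
    assert count_parameters(cfg) == embed_n + 2 * per_round + head


def test_single_conv_parameter_arithmetic():
    # a lone 1x1 convolution 4 -> 2 with bias carries 4*2 + 2 = 10 scalars
    cfg = ModelConfig(in_channels=4, embed_width=8, stage2_width=16,
                      classifier_hidden=16)
    store = ParameterStore.initialize(cfg, seed=0)
    assert store.params["embed.skip.w"].size + store.params["embed.skip.b"].size \
        == 4 * 8 + 8
    assert store.params["round0.dw.w"].size + store.params["round0.dw.b"].size \
        == 16 * 3 + 16


ABLATION_CASES = [
    {"use_embedding": False},
    {"conv_type": "sc"},
    {"use_dafm": False},
    {"n_levels": 4},
    {"use_cot": False},
    {"rounds": 1},
    {"rounds": 3},
]


@pytest.mark.parametrize("overrides", ABLATION_CASES,
                         ids=lambda o: ",".join(f"{k}={v}" for k, v in o.items()))
def test_ablation_variants_run_forward_and_backward(overrides, rng):
    cfg = ModelConfig(in_channels=4, embed_width=8, stage2_width=16,
                      classifier_hidden=16, **overrides)
    store = ParameterStore.initialize(cfg, seed=0)
    x = rng.standard_normal((2, 4, 64)).astype(np.float32)
    tp = _lift_params(store, requires_grad=True)
    out = forward_core(Tensor(x), cfg, tp, store, train=True)
    assert out.shape == (2, 2)
    out.sum().backward()
    grads = [t.grad for t in tp.values() if t.grad is not None]
    assert grads and all(np.all(np.isfinite(g)) for g in grads)


def test_gradients_match_finite_differences():
    """Full-model loss gradient vs central differences in double precision."""
    cfg = ModelConfig(in_channels=4, embed_width=4, stage2_width=8,
                      cot_groups=2, classifier_hidden=8)
    store = ParameterStore.initialize(cfg, seed=2, dtype=np.float64)
    rng = np.random.default_rng(0)
    # break the zero-bias symmetry so bias gradients are informative
    for k, v in store.params.items():
        store.params[k] = v + 0.05 * rng.standard_normal(v.shape)
    x = rng.standard_normal((3, 4, 32))
    y = np.array([0, 1, 0])

    def loss_value() -> float:
        tp = _lift_params(store, requires_grad=False)
        logits = forward_core(Tensor(x), cfg, tp, store, train=False)
        z = logits.data
        return float(np.mean(np.log(np.sum(np.exp(z), axis=1)) - z[np.arange(3), y]))

    tp = _lift_params(store, requires_grad=True)
    logits = forward_core(Tensor(x), cfg, tp, store, train=False)
    onehot = np.zeros((3, 2))
    onehot[np.arange(3), y] = 1.0
    loss = (logits.logsumexp(axis=1) - (logits * onehot).sum(axis=1)).mean()
    loss.backward()

    check_rng = np.random.default_rng(1)
    worst = 0.0
    for name, t in tp.items():
        flat = store.params[name].reshape(-1)
        for idx in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
            eps = 1e-4
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss_value()
            flat[idx] = orig - eps
            lm = loss_value()
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            an = t.grad.reshape(-1)[idx]
            rel = abs(fd - an) / max(abs(fd), abs(an), 1e-8)
            worst = max(worst, rel)
    assert worst < 1e-3


def test_checkpoint_roundtrip_bit_exact(tmp_path, small_cfg, small_store, rng):
    path = tmp_path / "model.h5"
    save_checkpoint(path, small_store, small_cfg)
    store2, cfg2 = load_checkpoint(path)
    assert cfg2 == small_cfg
    for k, v in small_store.params.items():
        np.testing.assert_array_equal(store2.params[k], v)
    x = fmap(rng, 4, 32)
    np.testing.assert_array_equal(forward(x, small_cfg, small_store),
                                  forward(x, cfg2, store2))


def test_model_summary_reports_total(small_cfg):
    text = model_summary(small_cfg)
    assert str(count_parameters(small_cfg)) in text
    assert "embed.conv1.w" in text


@pytest.mark.parametrize("kwargs", [
    {"stage2_width": 30, "n_levels": 4},
    {"stage2_width": 30, "cot_groups": 4},
    {"cot_kernel": 4},
    {"rounds": 0},
    {"conv_type": "huge"},
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelConfig(in_channels=4, **kwargs)
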