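"""TSD-Net blocks against independent oracles, shape contracts and
parameter/MAC accounting."""

import numpy as np
import pytest

import apneakit.nn as nn
from apneakit.nn import Tensor
from apneakit.tsdnet import (MHCE, CSEF, MHSABlock, MSCABlock, SEBlock, TSDNet,
                             TSDNetConfig, count_params_macs,
                             extract_stage4_features, tsdnet_b, tsdnet_t,
                             tsdnet_reduced)

RNG = np.random.default_rng(0)


def tiny_cfg(**kw):
    base = dict(stage_dims=(8, 16, 32, 64), stage3_blocks=(1, 1), variant="tiny")
    base.update(kw)
    return TSDNetConfig(**base)


# ---------------------------------------------------------------------------
# MHCE
# ---------------------------------------------------------------------------

def _naive_mhce(x, convs, group):
    """Independent oracle: per-head, per-channel direct 1-D convolution."""
    b, c, l = x.shape
    out = np.zeros_like(x)
    for j, conv in enumerate(convs):
        w = conv.w.data
        bias = conv.b.data
        k = w.shape[2]
        pad = k // 2
        for ci in range(group):
            ch = j * group + ci
            xp = np.pad(x[:, ch], ((0, 0), (pad, pad)))
            for p in range(l):
                out[:, ch, p] = (xp[:, p:p + k] * w[ci, 0]).sum(axis=1) + bias[ci]
    return out


@pytest.mark.parametrize("c,heads,l", [(4, 2, 8), (8, 4, 16), (4, 4, 12)])
def test_mhce_matches_naive_per_head_convolution(c, heads, l):
    rng = np.random.default_rng(c * 100 + l)
    mhce = MHCE(rng, c, heads, kernels=tuple(3 + 2 * j for j in range(heads)))
    x = rng.normal(size=(2, c, l))
    got = mhce(Tensor(x)).data
    want = _naive_mhce(x, mhce.convs, c // heads)
    np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)
    assert got.shape == x.shape


def test_mhce_identity_kernel_preserves_input():
    rng = np.random.default_rng(1)
    mhce = MHCE(rng, 4, 1, kernels=(3,))
    mhce.convs[0].w.data[:] = 0.0
    mhce.convs[0].w.data[:, 0, 1] = 1.0      # centred delta
    mhce.convs[0].b.data[:] = 0.0
    x = rng.normal(size=(3, 4, 10))
    np.testing.assert_allclose(mhce(Tensor(x)).data, x, atol=1e-6)


def test_mhce_rejects_indivisible_channels():
    with pytest.raises(ValueError):
        MHCE(np.random.default_rng(0), 6, 4, (3, 5, 7, 9))


# ---------------------------------------------------------------------------
# CSEF
# ---------------------------------------------------------------------------

def test_csef_grouping_gathers_one_channel_per_head():
    # C=4, N=2 heads of size 2: group 0 = channels (0, 2), group 1 = (1, 3)
    idx = CSEF.grouping_indices(4, 2)
    np.testing.assert_array_equal(idx, [0, 2, 1, 3])


@pytest.mark.parametrize("c,heads", [(4, 2), (8, 4), (16, 4), (64, 8)])
def test_csef_grouping_is_a_bijection(c, heads):
    idx = CSEF.grouping_indices(c, heads)
    assert sorted(idx) == list(range(c))
    inverse = np.argsort(idx)
    np.testing.assert_array_equal(idx[inverse], np.arange(c))


def test_csef_single_head_grouping_degenerates_to_identity():
    rng = np.random.default_rng(2)
    csef = CSEF(rng, 4, 1, expand=2)
    np.testing.assert_array_equal(csef.gather_idx, np.arange(4))
    x = rng.normal(size=(2, 4, 6))
    want = csef.w_agg(csef.w_group_out(nn.gelu(csef.w_group_in(Tensor(x))))).data
    np.testing.assert_allclose(csef(Tensor(x)).data, want, atol=1e-6)


def test_csef_preserves_shape():
    rng = np.random.default_rng(3)
    csef = CSEF(rng, 8, 4, expand=2)
    x = rng.normal(size=(2, 8, 5))
    assert csef(Tensor(x)).data.shape == x.shape


# ---------------------------------------------------------------------------
# SE
# ---------------------------------------------------------------------------

def test_se_gate_forced_to_one_is_identity():
    rng = np.random.default_rng(4)
    se = SEBlock(rng, 4, reduction=2)
    se.fc2.w.data[:] = 0.0
    se.fc2.b.data[:] = 100.0                 # sigmoid -> 1
    x = rng.normal(size=(2, 4, 6))
    np.testing.assert_allclose(se(Tensor(x)).data, x, rtol=1e-5)


def test_se_output_bounded_by_input_elementwise():
    rng = np.random.default_rng(5)
    se = SEBlock(rng, 8, reduction=4)
    x = rng.normal(size=(3, 8, 10))
    y = se(Tensor(x)).data
    assert np.all(np.abs(y) <= np.abs(x) + 1e-12)


def test_se_two_channel_case_matches_scalar_oracle():
    rng = np.random.default_rng(6)
    se = SEBlock(rng, 2, reduction=1)
    x = rng.normal(size=(1, 2, 4))
    pooled = x.mean(axis=2)[0]
    h = np.maximum(pooled @ se.fc1.w.data + se.fc1.b.data, 0.0)
    gate = 1.0 / (1.0 + np.exp(-(h @ se.fc2.w.data + se.fc2.b.data)))
    want = x * gate[None, :, None]
    np.testing.assert_allclose(se(Tensor(x)).data, want, rtol=1e-5)


# ---------------------------------------------------------------------------
# MSCA / MHSA blocks
# ---------------------------------------------------------------------------

class _Identity(nn.Module):
    def forward(self, x):
        return x


def test_msca_forced_composition_is_elementwise_square():
    """With the norm, branch convolutions, SE and feed-forward all forced to
    identities, the block computes x + (W_s x) ⊙ (W_v x) = x + x ⊙ x."""
    rng = np.random.default_rng(7)
    blk = MSCABlock(rng, 4, heads=2, kernels=(3, 5), expand=2, mlp_ratio=2,
                    se_reduction=2)
    blk.ln1 = _Identity()
    blk.mhce = _Identity()
    blk.csef = _Identity()
    blk.se = _Identity()
    for conv in (blk.w_s, blk.w_v):
        conv.w.data[:] = np.eye(4)[:, :, None]
        conv.b.data[:] = 0.0
    blk.ff2.w.data[:] = 0.0
    blk.ff2.b.data[:] = 0.0
    x = rng.normal(size=(2, 4, 6))
    np.testing.assert_allclose(blk(Tensor(x)).data, x + x * x, rtol=1e-5,
                               atol=1e-6)


def test_msca_retains_modulation_branch_and_gradients_flow():
    rng = np.random.default_rng(8)
    blk = MSCABlock(rng, 8, heads=4, kernels=(3, 5, 7, 9), expand=2,
                    mlp_ratio=2, se_reduction=4)
    x = Tensor(rng.normal(size=(2, 8, 12)))
    out = blk(x)
    assert out.shape == x.shape
    assert blk.last_attention.shape == (2, 8, 12)
    (out.power(2)).sum().backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), name


def test_mhsa_attention_rows_are_stochastic_and_single_token_trivial():
    rng = np.random.default_rng(9)
    blk = MHSABlock(rng, 8, heads=2, mlp_ratio=2)
    x = Tensor(rng.normal(size=(2, 8, 6)))
    blk(x)
    rows = blk.last_attention.sum(axis=-1)
    np.testing.assert_allclose(rows, 1.0, atol=1e-5)
    blk(Tensor(rng.normal(size=(1, 8, 1))))
    np.testing.assert_allclose(blk.last_attention, 1.0, atol=1e-6)


def test_mhsa_two_token_case_matches_scalar_softmax_oracle():
    rng = np.random.default_rng(10)
    blk = MHSABlock(rng, 2, heads=1, mlp_ratio=1)
    x = rng.normal(size=(1, 2, 2))
    blk(Tensor(x))
    # oracle: replicate LN -> qkv -> scaled scores -> softmax by hand
    mu = x.mean(axis=1, keepdims=True)
    sd = np.sqrt(x.var(axis=1, keepdims=True) + 1e-5)
    t = ((x - mu) / sd * blk.ln1.gamma.data[None, :, None]
         + blk.ln1.beta.data[None, :, None])[0].T        # [L, C]
    qkv = t @ blk.qkv.w.data + blk.qkv.b.data
    q, k = qkv[:, :2], qkv[:, 2:4]
    scores = q @ k.T / np.sqrt(2.0)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    want = e / e.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(blk.last_attention[0, 0], want, rtol=1e-4,
                               atol=1e-5)


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

def test_stage_trace_matches_documented_feature_map_sizes():
    net = TSDNet(tsdnet_reduced(), seed=0)
    x = Tensor(RNG.normal(size=(3, 1, 256)))
    dims = tsdnet_reduced().stage_dims
    assert net.stage_trace(x) == [(dims[0], 64), (dims[1], 32),
                                  (dims[2], 16), (dims[3], 8)]


def test_forward_outputs_probability_attention_and_features():
    net = TSDNet(tiny_cfg(), seed=1)
    net.eval()
    x = Tensor(RNG.normal(size=(4, 1, 256)))
    prob, stack, s4 = net.forward_full(x)
    assert prob.shape == (4,)
    assert np.all((prob.data > 0) & (prob.data < 1))
    assert [m.shape[-1] for m in stack.maps] == [64, 32, 16, 8]
    assert s4.shape == (4, 64, 8)
    with pytest.raises(ValueError, match="expected input"):
        net(Tensor(RNG.normal(size=(2, 1, 128))))


def test_forward_deterministic_in_eval_mode():
    net = TSDNet(tiny_cfg(), seed=2)
    net.eval()
    x = Tensor(RNG.normal(size=(2, 1, 256)))
    np.testing.assert_array_equal(net(x).data, net(x).data)


def test_untrained_network_is_a_null_classifier():
    net = TSDNet(tiny_cfg(), seed=3)
    net.eval()
    rng = np.random.default_rng(42)
    x = rng.normal(size=(2000, 1, 256))
    y = np.tile([0, 1], 1000)
    from apneakit.trainer import predict_epoch_probs
    from apneakit.metrics import auc

    p = predict_epoch_probs(net, x)
    assert abs(auc(p, y) - 0.5) <= 0.05


def test_extract_stage4_features_pools_channels():
    ones = np.ones((2, 512, 8))
    np.testing.assert_array_equal(extract_stage4_features(ones), np.ones((2, 8)))
    toy = np.arange(6, dtype=float).reshape(1, 2, 3)
    np.testing.assert_allclose(extract_stage4_features(toy),
                               toy.mean(axis=1))
    assert extract_stage4_features(np.zeros((5, 64, 8))).shape == (5, 8)


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def test_linear_and_depthwise_closed_form_counts():
    rng = np.random.default_rng(0)
    lin = nn.Linear(rng, 10, 1)
    assert lin.w.data.size + lin.b.data.size == 11
    conv = nn.Conv1d(rng, 6, 6, 5, groups=6, bias=False)
    assert conv.w.data.size == 6 * 5
    # depthwise "same" conv MAC count = C * k * L
    from apneakit.tsdnet import _msca_macs

    base = _msca_macs(8, 16, 2, (3, 3), 2, 2, 4)
    plus = _msca_macs(8, 16, 2, (3, 5), 2, 2, 4)
    assert plus - base == (8 // 2) * 2 * 16


def test_doubling_dims_roughly_quadruples_parameters():
    small = tiny_cfg()
    big = tiny_cfg(stage_dims=(16, 32, 64, 128))
    p_small, _ = count_params_macs(small)
    p_big, _ = count_params_macs(big)
    assert abs(p_big / p_small - 4.0) < 0.4      # within 10%


def test_variant_configs_validate_and_reduced_is_instantiable():
    with pytest.raises(ValueError):
        TSDNetConfig(stage_dims=(64, 100, 200, 400))
    with pytest.raises(ValueError):
        TSDNetConfig(mlp_ratio=0)
    for cfg in (tsdnet_t(), tsdnet_b(), tsdnet_reduced()):
        assert cfg.head_kernels(4) == (3, 5, 7, 9)
    uni = TSDNetConfig(multiscale_kernels=False)
    assert uni.head_kernels(4) == (3, 3, 3, 3)
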