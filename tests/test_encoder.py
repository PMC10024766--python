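"""Encoder stage contracts: attention behaviour, MAM identities, resolution
schedule, and equivalence with an explicit loop-based forward pass."""

import numpy as np
import pytest

from litesal import EncoderConfig, nn
from litesal.encoder import ChannelAttention, Encoder, MultiscaleAttention, SpatialAttention
from litesal.nn import Tensor, zero_module

from _oracles import (
    naive_batchnorm_train,
    naive_bilinear_resize,
    naive_adaptive_avgpool,
    naive_conv2d,
    naive_relu,
    naive_sigmoid,
)


def small_cfg(**kw):
    base = dict(
        stage_channels=[4, 4, 8, 8, 128],
        blocks_per_stage=[1, 1, 1, 1, 1],
        dilation_rates=[1, 2, 4],
        attention_reduction=2,
    )
    base.update(kw)
    return EncoderConfig(**base)


# -- channel attention -------------------------------------------------------

def test_channel_attention_shape_and_range(rng):
    att = ChannelAttention(64, 4, np.random.default_rng(0))
    x = Tensor(rng.standard_normal((2, 64, 28, 28)).astype(np.float32))
    w = att(x)
    assert w.shape == (2, 64, 1, 1)
    assert (w.data > 0).all() and (w.data < 1).all()


def test_channel_attention_symmetric_weights_give_equal_attention():
    # zeroed MLP: every channel sees the same affine map -> equal weights
    att = ChannelAttention(8, 2, np.random.default_rng(0))
    zero_module(att)
    x = Tensor(np.random.default_rng(1).standard_normal((1, 8, 4, 4)).astype(np.float32))
    w = att(x).data.reshape(-1)
    np.testing.assert_allclose(w, w[0], atol=1e-7)


def test_channel_attention_matches_pool_affine_sigmoid_loop():
    att = ChannelAttention(2, 1, np.random.default_rng(0))
    x = np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2) / 8.0
    got = att(Tensor(x)).data.reshape(2)
    # explicit loop: pool -> fc1 -> relu -> fc2 -> sigmoid
    pooled = [float(x[0, c].mean()) for c in range(2)]
    w1, b1 = att.fc1.weight.data, att.fc1.bias.data
    w2, b2 = att.fc2.weight.data, att.fc2.bias.data
    hidden = [max(0.0, sum(pooled[i] * w1[i, j] for i in range(2)) + b1[j])
              for j in range(w1.shape[1])]
    out = [sum(hidden[j] * w2[j, k] for j in range(len(hidden))) + b2[k] for k in range(2)]
    want = naive_sigmoid(np.array(out))
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_channel_attention_rejects_nonfinite():
    att = ChannelAttention(2, 1, np.random.default_rng(0))
    bad = np.full((1, 2, 2, 2), np.nan, dtype=np.float32)
    with pytest.raises(ValueError, match="invalid activations"):
        att(Tensor(bad))


# -- spatial attention -------------------------------------------------------

def test_spatial_attention_shape_and_constant_input(rng):
    att = SpatialAttention(np.random.default_rng(0))
    x = Tensor(rng.standard_normal((1, 96, 14, 14)).astype(np.float32))
    w = att(x)
    assert w.shape == (1, 1, 14, 14)
    # translation symmetry holds away from the zero-padded border
    const = att(Tensor(np.full((1, 96, 14, 14), 0.7, dtype=np.float32))).data
    interior = const[0, 0, 1:-1, 1:-1]
    np.testing.assert_allclose(interior, interior.flat[0], atol=1e-6)


def test_spatial_attention_matches_conv_loop():
    att = SpatialAttention(np.random.default_rng(3))
    x = np.random.default_rng(4).standard_normal((1, 1, 2, 2)).astype(np.float32)
    got = att(Tensor(x)).data
    squeezed = np.concatenate([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
    conv = naive_conv2d(squeezed, att.conv.weight.data, att.conv.bias.data, padding=1)
    np.testing.assert_allclose(got, naive_sigmoid(conv), atol=1e-6)


# -- multiscale attention module --------------------------------------------

def naive_mam_forward(mam: MultiscaleAttention, x: np.ndarray) -> np.ndarray:
    """Loop-oracle MAM: shared conv, 3 scale branches, attention softmax,
    fuse, residual — using only the naive reference ops."""
    h, w = x.shape[2], x.shape[3]
    sh = naive_conv2d(x, mam.shared.conv.weight.data, padding=1)
    sh = naive_relu(
        naive_batchnorm_train(sh, mam.shared.bn.weight.data, mam.shared.bn.bias.data)
    )
    feats = []
    for i, conv in enumerate(mam.branches):
        d = conv.dilation
        if i == 0:
            src = naive_bilinear_resize(sh, 2 * h, 2 * w)
        elif i == 1:
            src = sh
        else:
            src = naive_adaptive_avgpool(sh, h // 2, w // 2)
        f = naive_conv2d(src, conv.weight.data, conv.bias.data, padding=d, dilation=d)
        if f.shape[2:] != (h, w):
            f = naive_bilinear_resize(f, h, w)
        feats.append(f)
    fused = feats[0] + feats[1] + feats[2]
    logits = []
    for i in range(3):
        ca, sa = mam.channel_att[i], mam.spatial_att[i]
        pooled = fused.mean(axis=(2, 3))
        hidden = naive_relu(pooled @ ca.fc1.weight.data + ca.fc1.bias.data)
        cw = naive_sigmoid(hidden @ ca.fc2.weight.data + ca.fc2.bias.data)
        squeezed = np.concatenate(
            [fused.mean(axis=1, keepdims=True), fused.max(axis=1, keepdims=True)], axis=1
        )
        sw = naive_sigmoid(naive_conv2d(squeezed, sa.conv.weight.data, sa.conv.bias.data, padding=1))
        logits.append(cw[:, :, None, None] * sw)
    stack = np.stack(logits)
    e = np.exp(stack - stack.max(axis=0, keepdims=True))
    s = e / e.sum(axis=0, keepdims=True)
    mixed = sum(feats[i] * s[i] for i in range(3))
    out = naive_conv2d(mixed, mam.fuse_conv.weight.data, padding=1)
    out = naive_batchnorm_train(out, mam.fuse_bn.weight.data, mam.fuse_bn.bias.data)
    return out + x


def test_mam_matches_loop_oracle(rng):
    cfg = small_cfg()
    mam = MultiscaleAttention(2, cfg, np.random.default_rng(7))
    x = rng.standard_normal((1, 2, 4, 4)).astype(np.float32)
    got = mam(Tensor(x)).data
    np.testing.assert_allclose(got, naive_mam_forward(mam, x), atol=1e-5)


def test_mam_zero_weights_is_identity(rng):
    mam = MultiscaleAttention(3, small_cfg(), np.random.default_rng(0))
    zero_module(mam)
    x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
    out = mam(Tensor(x)).data
    np.testing.assert_array_equal(out, x)


@pytest.mark.parametrize("shape", [(1, 2, 4, 4), (2, 3, 6, 6), (1, 4, 7, 7), (1, 2, 5, 9)])
def test_mam_preserves_shape(rng, shape):
    mam = MultiscaleAttention(shape[1], small_cfg(), np.random.default_rng(1))
    assert mam(Tensor(rng.standard_normal(shape).astype(np.float32))).shape == shape


def test_mam_branch_weights_sum_to_one(rng):
    mam = MultiscaleAttention(4, small_cfg(), np.random.default_rng(2))
    x = Tensor(rng.standard_normal((2, 4, 6, 6)).astype(np.float32))
    weights = mam.branch_weights(x)
    total = sum(w.data for w in weights)
    np.testing.assert_allclose(total, 1.0, atol=1e-6)
    assert all((w.data >= 0).all() for w in weights)


def test_mam_rejects_single_pixel_axes():
    mam = MultiscaleAttention(2, small_cfg(), np.random.default_rng(0))
    with pytest.raises(ValueError, match="stage resolution"):
        mam(Tensor(np.zeros((1, 2, 1, 4), dtype=np.float32)))


def test_mam_branch_count_is_fixed():
    with pytest.raises(ValueError):
        EncoderConfig(dilation_rates=[1, 2])


# -- encoder ------------------------------------------------------------------

def test_encoder_resolution_schedule_and_terminal_width(default_model):
    x = Tensor(np.random.default_rng(0).random((1, 3, 224, 224), dtype=np.float32))
    with nn.no_grad():
        maps = default_model.encoder(x)
    assert [m.shape[2] for m in maps] == [112, 56, 28, 14, 7]
    assert [m.shape[3] for m in maps] == [112, 56, 28, 14, 7]
    assert maps[4].shape[1] == 128
    assert all(np.isfinite(m.data).all() for m in maps)


def test_encoder_rejects_wrong_input_size():
    enc = Encoder(small_cfg(), np.random.default_rng(0))
    with pytest.raises(ValueError, match="224x224"):
        enc(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
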