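"""Decoder contracts: pyramid pooling, resize-adjust, full-scale skip wiring,
channel economy, residual pass-through, and loop-oracle equivalence."""

import numpy as np
import pytest

from litesal import DecoderConfig, EncoderConfig, nn
from litesal.decoder import (
    SCM_CARRIED,
    SCM_SOURCES,
    Decoder,
    PredictHead,
    PyramidPooling,
    ResizeAdjust,
    SCMStage,
    resize_adjust,
)
from litesal.nn import Tensor, zero_module

from _oracles import (
    naive_adaptive_avgpool,
    naive_batchnorm_train,
    naive_bilinear_resize,
    naive_conv2d,
    naive_relu,
    naive_sigmoid,
)


# -- pyramid pooling ----------------------------------------------------------

def test_ppm_preserves_shape(rng):
    ppm = PyramidPooling(128, [1, 2, 3, 6], np.random.default_rng(0))
    x = Tensor(rng.standard_normal((1, 128, 7, 7)).astype(np.float32))
    assert ppm(x).shape == (1, 128, 7, 7)


def test_ppm_constant_input_gives_spatially_constant_output():
    ppm = PyramidPooling(8, [1, 2], np.random.default_rng(0))
    x = Tensor(np.full((1, 8, 4, 4), 0.3, dtype=np.float32))
    out = ppm(x).data
    # pooling/1x1 convs of a constant are constant; only the BN-ReLU projection
    # rescales, uniformly over space (1x1 projection -> no border effects)
    assert np.abs(out - out[:, :, :1, :1]).max() < 1e-5


def test_ppm_rejects_oversized_bin():
    ppm = PyramidPooling(8, [8], np.random.default_rng(0))
    with pytest.raises(ValueError, match="bin"):
        ppm(Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))


def test_ppm_matches_loop_oracle(rng):
    ppm = PyramidPooling(4, [1, 2], np.random.default_rng(5))
    x = rng.standard_normal((1, 4, 4, 4)).astype(np.float32)
    got = ppm(Tensor(x)).data

    parts = [x.astype(np.float64)]
    for b, conv in zip(ppm.bins, ppm.branch_convs):
        pooled = naive_adaptive_avgpool(x, b, b)
        proj = naive_conv2d(pooled, conv.weight.data, conv.bias.data)
        parts.append(naive_bilinear_resize(proj, 4, 4))
    cat = np.concatenate(parts, axis=1)
    out = naive_conv2d(cat, ppm.project.conv.weight.data)
    out = naive_relu(
        naive_batchnorm_train(out, ppm.project.bn.weight.data, ppm.project.bn.bias.data)
    )
    np.testing.assert_allclose(got, out, atol=1e-5)


# -- resize_adjust ------------------------------------------------------------

def test_resize_adjust_contract(rng):
    ra = ResizeAdjust(128, 24, np.random.default_rng(0))
    x = Tensor(rng.standard_normal((1, 128, 7, 7)).astype(np.float32))
    assert ra(x, (14, 14)).shape == (1, 24, 14, 14)


def test_resize_adjust_identity_when_shape_matches(rng):
    x = Tensor(rng.standard_normal((1, 8, 5, 5)).astype(np.float32))
    out = resize_adjust(x, (5, 5))
    np.testing.assert_array_equal(out.data, x.data)


def test_resize_adjust_rejects_bad_target(rng):
    x = Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32))
    with pytest.raises(ValueError):
        resize_adjust(x, (0, 4))


# -- SCM stages ---------------------------------------------------------------

def _toy_stage():
    return SCMStage(
        width=8, source_channels=[4, 4, 4, 4], carried_channels=6,
        reduce_fraction=0.25, rng=np.random.default_rng(11),
    )


def test_scm_requires_four_sources(rng):
    stage = _toy_stage()
    carried = Tensor(rng.standard_normal((1, 6, 2, 2)).astype(np.float32))
    srcs = [Tensor(rng.standard_normal((1, 4, 2, 2)).astype(np.float32)) for _ in range(3)]
    with pytest.raises(ValueError, match="4 sources"):
        stage(carried, srcs, (2, 2))


def test_scm_zeroed_fusion_is_residual_passthrough(rng):
    stage = _toy_stage()
    zero_module(stage.fuse)
    for red in stage.reducers:
        zero_module(red)
    carried = Tensor(rng.standard_normal((1, 6, 2, 2)).astype(np.float32))
    srcs = [Tensor(rng.standard_normal((1, 4, 4, 4)).astype(np.float32)) for _ in range(4)]
    out = stage(carried, srcs, (4, 4))
    want = stage.carry(carried, (4, 4))
    np.testing.assert_array_equal(out.data, want.data)


def test_scm_concat_width_equals_stage_width():
    # anti-explosion economy: 4 quarter-width sources concatenate to exactly
    # the stage width before fusion
    for width in (96, 64, 32, 16):
        stage = SCMStage(width, [4, 4, 4, 4], 6, 0.25, np.random.default_rng(0))
        assert stage.quarter * 4 == width
        assert stage.fuse.conv.weight.shape[1] == width


def test_scm_matches_loop_oracle(rng):
    stage = _toy_stage()
    carried = rng.standard_normal((1, 6, 2, 2)).astype(np.float32)
    srcs = [rng.standard_normal((1, 4, 2, 2)).astype(np.float32) for _ in range(4)]
    got = stage(Tensor(carried), [Tensor(s) for s in srcs], (2, 2)).data

    reduced = [
        naive_conv2d(s, red.weight.data, red.bias.data)
        for red, s in zip(stage.reducers, srcs)
    ]
    cat = np.concatenate(reduced, axis=1)
    fused = naive_conv2d(cat, stage.fuse.conv.weight.data, padding=1)
    fused = naive_relu(
        naive_batchnorm_train(fused, stage.fuse.bn.weight.data, stage.fuse.bn.bias.data)
    )
    carry = naive_conv2d(carried, stage.carry.proj.weight.data, stage.carry.proj.bias.data)
    np.testing.assert_allclose(got, fused + carry, atol=1e-5)


# -- decoder wiring -----------------------------------------------------------

def test_full_scale_coverage_of_wiring_table():
    fed = set()
    for stage in (4, 3, 2, 1):
        fed.update(SCM_SOURCES[stage])
        fed.add(SCM_CARRIED[stage])
    # every shallow/same-scale encoder stage feeds the decoder somewhere
    assert {"en1", "en2", "en3", "en4"} <= fed
    # P reaches every decoder stage (as source or carried feature)
    for stage in (4, 3, 2, 1):
        assert "P" in SCM_SOURCES[stage] or SCM_CARRIED[stage] == "P"


def _tiny_encoder_maps(rng):
    cfg = EncoderConfig(stage_channels=[4, 4, 8, 8, 128],
                        blocks_per_stage=[1, 1, 1, 1, 1])
    shapes = [(1, c, r, r) for c, r in zip(cfg.stage_channels, (112, 56, 28, 14, 7))]
    return cfg, [Tensor(rng.standard_normal(s).astype(np.float32)) for s in shapes]


def test_decoder_stage_resolutions_and_determinism(rng):
    enc_cfg, maps = _tiny_encoder_maps(rng)
    dec = Decoder(enc_cfg, DecoderConfig(stage_channels=[8, 8, 8, 8]),
                  np.random.default_rng(3))
    with nn.no_grad():
        state1 = dec(maps)
        state2 = dec(maps)
    res = [m.shape[2] for m in state1["stage_outputs"]]
    assert res == [14, 28, 56, 112]
    assert state1["ppm_out"].shape == (1, 128, 7, 7)
    for a, b in zip(state1["stage_outputs"], state2["stage_outputs"]):
        np.testing.assert_array_equal(a.data, b.data)  # pure function of inputs


def test_decoder_requires_five_maps(rng):
    enc_cfg, maps = _tiny_encoder_maps(rng)
    dec = Decoder(enc_cfg, DecoderConfig(stage_channels=[8, 8, 8, 8]),
                  np.random.default_rng(3))
    with pytest.raises(ValueError, match="5 encoder"):
        dec(maps[:4])


# -- prediction head ----------------------------------------------------------

def test_predict_head_zero_logits_give_half_probability():
    head = PredictHead(4, np.random.default_rng(0))
    zero_module(head)
    x = Tensor(np.random.default_rng(1).standard_normal((1, 4, 112, 112)).astype(np.float32))
    prob = nn.sigmoid(head(x))
    assert prob.shape == (1, 1, 224, 224)
    np.testing.assert_allclose(prob.data, 0.5, atol=1e-7)


def test_predict_head_matches_scalar_sigmoid():
    head = PredictHead(1, np.random.default_rng(2))
    x = np.random.default_rng(3).standard_normal((1, 1, 2, 2)).astype(np.float32)
    got = nn.sigmoid(head(Tensor(x))).data
    logits = naive_conv2d(x, head.conv.weight.data, head.conv.bias.data, padding=1)
    want = naive_sigmoid(naive_bilinear_resize(logits, 4, 4))
    np.testing.assert_allclose(got, want, atol=1e-6)
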