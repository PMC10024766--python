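"""Lightweight five-stage encoder with multiscale attention modules (MAM).

Each stage halves the spatial resolution with a stride-2 entry convolution
and widens the channels only moderately (default 16-32-64-96-128, ending at
the published 7x7x128 for a 224x224 input).  The stage then passes its
feature map through a MAM: a shared conv-BN-ReLU, three dilated-convolution
branches evaluated at 2x / 1x / 0.5x spatial scale, channel-and-spatial
self-attention per branch, a softmax across the three branches (so the
attention selects among scales), a fusing convolution, and a residual
addition of the stage input.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import EncoderConfig
from .nn import Tensor


def _check_finite(x: Tensor) -> None:
    if not np.isfinite(x.data).all():
        raise ValueError("invalid activations")


class ChannelAttention(nn.Module):
    """Squeeze (global average pool) -> bottleneck MLP -> sigmoid weights.

    Returns one weight in [0, 1] per channel, shaped (N, C, 1, 1) so it
    rescales channels when applied multiplicatively.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        n, c = x.shape[0], x.shape[1]
        squeezed = nn.global_avg_pool(x)           # (N, C)
        w = nn.sigmoid(self.fc2(nn.relu(self.fc1(squeezed))))
        return nn.reshape(w, (n, c, 1, 1))


class SpatialAttention(nn.Module):
    """Channel mean+max squeeze -> 3x3 conv -> sigmoid weight per location."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 3, rng, padding=1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        mean_c = nn.tmean(x, axis=1, keepdims=True)
        max_c = nn.amax(x, axis=1, keepdims=True)
        return nn.sigmoid(self.conv(nn.concat([mean_c, max_c], axis=1)))


class MultiscaleAttention(nn.Module):
    """MAM: three dilated scale branches gated by a cross-branch softmax."""

    def __init__(self, channels: int, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.shared = nn.ConvBNReLU(channels, channels, rng)
        self.branches = nn.ModuleList(
            [
                nn.Conv2d(channels, channels, 3, rng, padding=d, dilation=d, bias=True)
                for d in cfg.dilation_rates
            ]
        )
        if len(self.branches) != 3:
            raise ValueError("the multiscale attention module has exactly 3 branches")
        self.channel_att = nn.ModuleList(
            [ChannelAttention(channels, cfg.attention_reduction, rng) for _ in range(3)]
        )
        self.spatial_att = nn.ModuleList([SpatialAttention(rng) for _ in range(3)])
        self.fuse_conv = nn.Conv2d(channels, channels, 3, rng, padding=1, bias=False)
        self.fuse_bn = nn.BatchNorm2d(channels)

    def branch_weights(self, x: Tensor) -> list[Tensor]:
        """The softmax-normalized per-branch attention maps S_i."""
        _, feats = self._branch_features(x)
        return self._attend(feats)

    def _branch_features(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        # the 0.5x branch floor-halves (adaptive pooling), so odd sizes such
        # as the 7x7 terminal stage are fine; only 1-pixel axes are not
        if h < 2 or w < 2:
            raise ValueError("stage resolution not divisible")
        shared = self.shared(x)
        up = nn.resize_bilinear(shared, (2 * h, 2 * w))
        f1 = nn.resize_bilinear(self.branches[0](up), (h, w))          # 2x scale
        f2 = self.branches[1](shared)                                   # 1x scale
        down = nn.adaptive_avg_pool2d(shared, (h // 2, w // 2))
        f3 = nn.resize_bilinear(self.branches[2](down), (h, w))         # 0.5x scale
        return shared, [f1, f2, f3]

    def _attend(self, feats: list[Tensor]) -> list[Tensor]:
        fused = feats[0] + feats[1] + feats[2]
        logits = [
            self.channel_att[i](fused) * self.spatial_att[i](fused) for i in range(3)
        ]
        return nn.softmax_list(logits)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x)
        _, feats = self._branch_features(x)
        weights = self._attend(feats)
        mixed = feats[0] * weights[0] + feats[1] * weights[1] + feats[2] * weights[2]
        return self.fuse_bn(self.fuse_conv(mixed)) + x


class EncoderStage(nn.Module):
    def __init__(self, cin: int, cout: int, blocks: int, cfg: EncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.entry = nn.ConvBNReLU(cin, cout, rng, stride=2)
        self.blocks = nn.ModuleList(
            [nn.ConvBNReLU(cout, cout, rng) for _ in range(blocks - 1)]
        )
        self.mam = MultiscaleAttention(cout, cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.entry(x)
        for blk in self.blocks:
            x = blk(x)
        return self.mam(x)


class Encoder(nn.Module):
    """224x224x3 image -> five feature maps at 112/56/28/14/7 resolution."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        chans = [3] + cfg.stage_channels
        self.stages = nn.ModuleList(
            [
                EncoderStage(chans[s], chans[s + 1], cfg.blocks_per_stage[s], cfg, rng)
                for s in range(5)
            ]
        )

    def forward(self, image: Tensor) -> list[Tensor]:
        if image.shape[2] != 224 or image.shape[3] != 224:
            raise ValueError("expected 224x224 input")
        maps = []
        x = image
        for stage in self.stages:
            x = stage(x)
            maps.append(x)
        return maps


def channel_attention(module: ChannelAttention, feature: Tensor) -> Tensor:
    """Functional wrapper: per-channel weights in [0, 1] for `feature`."""
    return module(feature)


def spatial_attention(module: SpatialAttention, feature: Tensor) -> Tensor:
    """Functional wrapper: per-location weight map in [0, 1] for `feature`."""
    return module(feature)
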