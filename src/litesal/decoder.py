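"""Full-scale skip-connection decoder (SCM) with pyramid pooling.

The deepest encoder map first passes a pyramid pooler P.  Four decoder
stages then run coarse-to-fine; stage i lives at encoder stage i's
resolution (X_de^4 at 14x14 ... X_de^1 at 112x112).  Each stage gathers four
source maps — same- and smaller-scale encoder features plus larger-scale
decoder features and P — reduces each to a quarter of the stage width,
resizes them to the stage resolution, concatenates, fuses with a 3x3
conv-BN-ReLU, and adds the carried feature (P or the previous decoder
stage) as a residual.  A small head turns X_de^1 into the 224x224 coarse
saliency logit map.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import DecoderConfig, EncoderConfig
from .nn import Tensor

# Wiring of Eqs.-style full-scale skips: per decoder stage, the carried
# residual feature and the four concatenated sources.  "enK" = encoder stage
# K output, "deK" = decoder stage K output, "P" = pyramid-pooled feature.
SCM_CARRIED = {4: "P", 3: "de4", 2: "de3", 1: "de2"}
SCM_SOURCES = {
    4: ("en4", "en3", "en2", "en1"),
    3: ("P", "en3", "en2", "en1"),
    2: ("P", "de4", "en2", "en1"),
    1: ("P", "de4", "de3", "en1"),
}


class PyramidPooling(nn.Module):
    """Multi-bin average pooling with per-bin projections (PSP-style)."""

    def __init__(self, channels: int, bins: list[int], rng: np.random.Generator):
        super().__init__()
        self.bins = list(bins)
        branch_c = max(1, channels // len(self.bins))
        self.branch_convs = nn.ModuleList(
            [nn.Conv2d(channels, branch_c, 1, rng, bias=True) for _ in self.bins]
        )
        self.project = nn.ConvBNReLU(
            channels + branch_c * len(self.bins), channels, rng, kernel_size=1
        )

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if any(b > min(h, w) for b in self.bins):
            raise ValueError("pyramid bin larger than spatial size")
        parts = [x]
        for b, conv in zip(self.bins, self.branch_convs):
            pooled = nn.adaptive_avg_pool2d(x, (b, b))
            parts.append(nn.resize_bilinear(conv(pooled), (h, w)))
        return self.project(nn.concat(parts, axis=1))


class ResizeAdjust(nn.Module):
    """R(.): bilinear resize plus 1x1 channel projection when widths differ."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.proj = None if cin == cout else nn.Conv2d(cin, cout, 1, rng, bias=True)

    def forward(self, x: Tensor, target_hw: tuple[int, int]) -> Tensor:
        if target_hw[0] < 1 or target_hw[1] < 1:
            raise ValueError("invalid resize target")
        x = nn.resize_bilinear(x, target_hw)
        return x if self.proj is None else self.proj(x)


def resize_adjust(x: Tensor, target_hw: tuple[int, int], proj: nn.Conv2d | None = None) -> Tensor:
    """Functional R(.): resize, then optional 1x1 projection."""
    if target_hw[0] < 1 or target_hw[1] < 1:
        raise ValueError("invalid resize target")
    out = nn.resize_bilinear(x, target_hw)
    return out if proj is None else proj(out)


class SCMStage(nn.Module):
    """One full-scale fusion stage: reduce, resize, concat, fuse, residual."""

    def __init__(
        self,
        width: int,
        source_channels: list[int],
        carried_channels: int,
        reduce_fraction: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        if len(source_channels) != 4:
            raise ValueError("SCM requires 4 sources")
        self.quarter = max(1, int(width * reduce_fraction))
        self.reducers = nn.ModuleList(
            [nn.Conv2d(c, self.quarter, 1, rng, bias=True) for c in source_channels]
        )
        self.fuse = nn.ConvBNReLU(self.quarter * 4, width, rng)
        self.carry = ResizeAdjust(carried_channels, width, rng)

    def forward(self, carried: Tensor, sources: list[Tensor],
                target_hw: tuple[int, int]) -> Tensor:
        if len(sources) != 4:
            raise ValueError("SCM requires 4 sources")
        reduced = [
            nn.resize_bilinear(red(src), target_hw)
            for red, src in zip(self.reducers, sources)
        ]
        fused = self.fuse(nn.concat(reduced, axis=1))
        return fused + self.carry(carried, target_hw)


class PredictHead(nn.Module):
    """X_de^1 -> 224x224 single-channel saliency logits (sigmoid upstream)."""

    def __init__(self, cin: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, 1, 3, rng, padding=1, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        return nn.resize_bilinear(self.conv(x), (2 * h, 2 * w))


class Decoder(nn.Module):
    """Pyramid pooling + four SCM stages, coarse (stage 4) to fine (stage 1)."""

    def __init__(self, enc_cfg: EncoderConfig, cfg: DecoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        enc_c = enc_cfg.stage_channels          # en1..en5
        dec_widths = cfg.stage_channels          # de4..de1
        self.ppm = PyramidPooling(enc_c[4], cfg.ppm_bins, rng)

        width_of = {
            "P": enc_c[4],
            "en1": enc_c[0], "en2": enc_c[1], "en3": enc_c[2], "en4": enc_c[3],
            "de4": dec_widths[0], "de3": dec_widths[1], "de2": dec_widths[2],
        }
        self.stages = nn.ModuleList()
        for idx, stage in enumerate((4, 3, 2, 1)):
            self.stages.append(
                SCMStage(
                    width=dec_widths[idx],
                    source_channels=[width_of[s] for s in SCM_SOURCES[stage]],
                    carried_channels=width_of[SCM_CARRIED[stage]],
                    reduce_fraction=cfg.reduce_fraction,
                    rng=rng,
                )
            )

    def forward(self, encoder_maps: list[Tensor]) -> dict[str, Tensor]:
        if len(encoder_maps) != 5:
            raise ValueError("decoder expects the 5 encoder stage outputs")
        en = {f"en{i+1}": m for i, m in enumerate(encoder_maps)}
        feats = dict(en)
        feats["P"] = self.ppm(en["en5"])
        outputs = []
        for idx, stage in enumerate((4, 3, 2, 1)):
            target = en[f"en{stage}"].shape[2:4]
            sources = [feats[name] for name in SCM_SOURCES[stage]]
            carried = feats[SCM_CARRIED[stage]]
            out = self.stages[idx](carried, list(sources), tuple(target))
            feats[f"de{stage}"] = out
            outputs.append(out)
        return {"ppm_out": feats["P"], "stage_outputs": outputs}
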