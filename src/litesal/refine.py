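"""Residual refinement module (RFM) and full-network assembly.

The RFM is a small symmetric encoder-decoder over the coarse saliency map:
five one-convolution encoder stages with 4/8/16/24/36 filters of size 3x3
(each conv-BN-ReLU, 2x2 max pool between stages) and a mirrored five-stage
decoder with bilinear upsampling, ending in a single-channel residual.  The
refined map is produced by adding that residual to the coarse prediction in
logit space and applying one final sigmoid, which keeps the output inside
[0, 1] by construction; a zeroed RFM therefore reproduces the coarse map
exactly.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .decoder import Decoder, PredictHead
from .encoder import Encoder
from .nn import Tensor


class ResidualRefiner(nn.Module):
    def __init__(self, filters: list[int], rng: np.random.Generator, in_channels: int = 1):
        super().__init__()
        self.filters = list(filters)
        self.depth = len(self.filters)
        enc_chans = [in_channels] + self.filters
        self.enc = nn.ModuleList(
            [nn.ConvBNReLU(enc_chans[i], enc_chans[i + 1], rng) for i in range(self.depth)]
        )
        dec_filters = self.filters[::-1]                       # e.g. 36,24,16,8,4
        dec_chans = [self.filters[-1]] + dec_filters
        self.dec = nn.ModuleList(
            [nn.ConvBNReLU(dec_chans[i], dec_chans[i + 1], rng) for i in range(self.depth)]
        )
        self.out_conv = nn.Conv2d(dec_filters[-1], 1, 3, rng, padding=1, bias=True)

    def forward(self, coarse: Tensor) -> Tensor:
        h, w = coarse.shape[2], coarse.shape[3]
        scale = 2 ** (self.depth - 1)
        if h % scale or w % scale:
            raise ValueError(f"refiner input must be divisible by {scale}")
        sizes = []
        x = coarse
        for i, stage in enumerate(self.enc):
            x = stage(x)
            if i < self.depth - 1:
                sizes.append(x.shape[2:4])
                x = nn.max_pool2d(x, 2)
        x = self.dec[0](x)
        for i, stage in enumerate(self.dec[1:], start=1):
            x = nn.resize_bilinear(x, tuple(sizes[-i]))
            x = stage(x)
        return self.out_conv(x)


class SaliencyNet(nn.Module):
    """Encoder + full-scale-skip decoder + residual refiner, end to end.

    ``forward`` maps an (N, 3, 224, 224) image batch to the pair
    (M_coarse, M_refine), both probability maps of shape (N, 1, 224, 224).
    """

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        self.cfg = cfg or ModelConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self.encoder = Encoder(self.cfg.encoder, rng)
        self.decoder = Decoder(self.cfg.encoder, self.cfg.decoder, rng)
        self.head = PredictHead(self.cfg.decoder.stage_channels[-1], rng)
        self.rfm = ResidualRefiner(self.cfg.rfm_filters, rng)

    def forward(self, image: Tensor) -> tuple[Tensor, Tensor]:
        maps = self.encoder(image)
        state = self.decoder(maps)
        coarse_logit = self.head(state["stage_outputs"][-1])
        coarse = nn.sigmoid(coarse_logit)
        residual_logit = self.rfm(coarse)
        refined = nn.sigmoid(coarse_logit + residual_logit)
        return coarse, refined


def model_forward(model: SaliencyNet, image: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
    """Run the full network on one image or batch (NCHW or CHW)."""
    x = nn.as_tensor(image)
    if x.ndim == 3:
        x = nn.reshape(x, (1,) + x.shape)
    return model(x)


def count_parameters(model: nn.Module) -> float:
    """Trainable parameter count in millions, rounded to one decimal."""
    total = sum(p.size for p in model.parameters())
    return round(total / 1e6, 1)


def count_parameters_exact(model: nn.Module) -> int:
    return int(sum(p.size for p in model.parameters()))
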