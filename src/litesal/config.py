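"""Configuration dataclasses for the model, metrics, training and synthesis.

Defaults encode the published recipe: a five-stage encoder ending at
7x7x128, quarter-width channel reduction before full-scale skip fusion,
refinement filters [4, 8, 16, 24, 36], Adam at 3e-4 with cosine annealing
over 60 epochs, and the standard saliency metric constants.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


def _as_list(x) -> list:
    return list(x)


@dataclass
class EncoderConfig:
    """Five stride-2 stages, each ending with a multiscale attention module.

    ``stage_channels`` must be non-decreasing and end at 128 (the published
    terminal width); ``blocks_per_stage`` is the depth knob used to land the
    assembled network on its 2.1 M parameter budget.
    """

    stage_channels: list[int] = field(default_factory=lambda: [16, 32, 64, 96, 128])
    blocks_per_stage: list[int] = field(default_factory=lambda: [1, 1, 1, 2, 2])
    dilation_rates: list[int] = field(default_factory=lambda: [1, 2, 4])
    attention_reduction: int = 4

    def __post_init__(self):
        self.stage_channels = _as_list(self.stage_channels)
        self.blocks_per_stage = _as_list(self.blocks_per_stage)
        self.dilation_rates = _as_list(self.dilation_rates)
        if len(self.stage_channels) != 5 or len(self.blocks_per_stage) != 5:
            raise ValueError("encoder needs exactly 5 stages")
        if any(c <= 0 for c in self.stage_channels) or any(b <= 0 for b in self.blocks_per_stage):
            raise ValueError("stage widths and depths must be positive")
        if any(b - a < 0 for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage_channels must be non-decreasing")
        if self.stage_channels[-1] != 128:
            raise ValueError("terminal encoder width must be 128")
        if len(self.dilation_rates) != 3:
            raise ValueError("the multiscale attention module has exactly 3 branches")
        if self.attention_reduction <= 0:
            raise ValueError("attention_reduction must be positive")


@dataclass
class DecoderConfig:
    """Full-scale skip-connection decoder: widths of X_de^4..X_de^1."""

    stage_channels: list[int] = field(default_factory=lambda: [96, 64, 32, 16])
    ppm_bins: list[int] = field(default_factory=lambda: [1, 2, 3, 6])
    reduce_fraction: float = 0.25

    def __post_init__(self):
        self.stage_channels = _as_list(self.stage_channels)
        self.ppm_bins = _as_list(self.ppm_bins)
        if len(self.stage_channels) != 4:
            raise ValueError("decoder has exactly 4 stages")
        if any(c <= 0 for c in self.stage_channels):
            raise ValueError("decoder widths must be positive")
        if any(b <= 0 for b in self.ppm_bins):
            raise ValueError("ppm bins must be positive")
        if not (0 < self.reduce_fraction <= 1):
            raise ValueError("reduce_fraction must be in (0, 1]")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    rfm_filters: list[int] = field(default_factory=lambda: [4, 8, 16, 24, 36])
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.encoder, dict):
            self.encoder = EncoderConfig(**self.encoder)
        if isinstance(self.decoder, dict):
            self.decoder = DecoderConfig(**self.decoder)
        self.rfm_filters = _as_list(self.rfm_filters)
        if len(self.rfm_filters) != 5 or any(f <= 0 for f in self.rfm_filters):
            raise ValueError("refinement module has 5 positive filter counts")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelConfig":
        return cls(**d)


@dataclass
class TrainConfig:
    lr0: float = 3e-4
    epochs: int = 60
    batch_size: int = 16
    flip_prob: float = 0.5
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (coarse, refine)
    hybrid_iou: bool = False  # optional BCE+IoU variant

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")
        self.loss_weights = tuple(self.loss_weights)


@dataclass
class MetricConfig:
    beta2_f: float = 0.3
    beta2_w: float = 1.0
    n_thresholds: int = 256
    sigma_w: float = 5.0           # std of the 7x7 dependency Gaussian
    alpha_w: float = math.log(0.5) / 5.0
    adaptive_threshold: bool = False

    def __post_init__(self):
        if self.beta2_f <= 0 or self.beta2_w <= 0:
            raise ValueError("beta2 values must be positive")
        if self.n_thresholds < 2:
            raise ValueError("need at least 2 thresholds")


@dataclass
class SynthConfig:
    n_images: int = 8
    image_size: int = 224
    mode: str = "xray"  # "blob" or "xray"
    contrast: float = 0.15
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.mode not in ("blob", "xray"):
            raise ValueError("mode must be 'blob' or 'xray'")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def model_config_from_yaml(path: str | Path) -> ModelConfig:
    d = load_yaml_config(path)
    return ModelConfig(**d.get("model", d))


def train_config_from_yaml(path: str | Path) -> TrainConfig:
    d = load_yaml_config(path)
    return TrainConfig(**d.get("train", d))
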