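"""Seeded synthetic (image, mask) generators.

Two scene families make every pipeline stage testable without downloads:

* ``blob`` — generic salient-object scenes: one to three smooth bright
  shapes (ellipses and radial-Fourier blobs, possibly clipped by the image
  border) over a textured background, mimicking ordinary SOD benchmarks.
* ``xray`` — pig-leg-radiograph-like images: a dark field, a brighter
  soft-tissue region bounded by a smooth random contour, and inside it an
  elongated curved "bone" tube (optionally branched) raised above the
  tissue by a small, controllable contrast, plus sensor noise.  The ground
  truth is the exact bone tube.

The X-ray generator is a statistical stand-in for a real pig-leg X-ray
collection: difficulty is controlled by ``contrast`` and ``noise_sigma``,
but no radiographic physics (beam hardening, scatter) is modelled.
Everything is a pure function of the configuration seed, down to the bytes
of the PNG files that :func:`gen_dataset` writes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import interpolate, ndimage

from .config import SynthConfig

FG_FRACTION_BOUNDS = (0.02, 0.6)
_MAX_TRIES = 64


@dataclass
class SamplePair:
    """One generated scene: float image in [0,1], binary mask, parameters."""

    image: np.ndarray                 # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray                  # (H, W) uint8 in {0, 1}
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        frac = float(self.mask.mean())
        if not (FG_FRACTION_BOUNDS[0] <= frac <= FG_FRACTION_BOUNDS[1]):
            raise ValueError(f"mask foreground fraction {frac:.3f} out of bounds")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    lo, hi = field_.min(), field_.max()
    return ((field_ - lo) / (hi - lo + 1e-12)).astype(np.float32)


def _radial_blob_mask(rng: np.random.Generator, size: int, center, r0: float) -> np.ndarray:
    """Smooth closed contour: radius modulated by a low-order Fourier series."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    r = np.full_like(theta, r0)
    for k in range(1, 5):
        amp = rng.normal(0.0, 0.10 / k) * r0
        phase = rng.uniform(0, 2 * np.pi)
        r = r + amp * np.cos(k * theta + phase)
    return (rad <= r).astype(np.uint8)


def _ellipse_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = rng.uniform(0.1 * size, 0.9 * size, size=2)
    a = rng.uniform(size / 12, size / 4)
    b = rng.uniform(size / 12, size / 4)
    phi = rng.uniform(0, np.pi)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def gen_blob_scene(cfg: SynthConfig, rng: np.random.Generator) -> SamplePair:
    """Generic salient-object scene: bright smooth shapes on textured ground."""
    size = cfg.image_size
    for _ in range(_MAX_TRIES):
        bg = 0.2 + 0.25 * _smooth_noise(rng, size, sigma=size / 8)
        n_shapes = int(rng.integers(1, 4))
        mask = np.zeros((size, size), dtype=np.uint8)
        for _ in range(n_shapes):
            if rng.random() < 0.5:
                mask |= _ellipse_mask(rng, size)
            else:
                center = rng.uniform(0.15 * size, 0.85 * size, size=2)
                mask |= _radial_blob_mask(rng, size, center, rng.uniform(size / 10, size / 5))
        frac = mask.mean()
        if not (FG_FRACTION_BOUNDS[0] <= frac <= FG_FRACTION_BOUNDS[1]):
            continue
        fg_value = min(1.0, 0.5 + 0.5 * cfg.contrast)
        texture = (1.0 - cfg.contrast) * 0.1 * _smooth_noise(rng, size, sigma=size / 16)
        img = bg.copy()
        img[mask == 1] = np.clip(fg_value + texture[mask == 1], 0.0, 1.0)
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        image = np.repeat(img[:, :, None], 3, axis=2)
        return SamplePair(image, mask, {"mode": "blob", "n_shapes": n_shapes,
                                        "fg_fraction": float(frac)})
    raise RuntimeError("could not generate a blob scene within bounds")


def _bone_curve(rng: np.random.Generator, allowed: np.ndarray, n_ctrl: int = 4):
    """Spline control points sampled inside the allowed (eroded-tissue) region."""
    ys, xs = np.nonzero(allowed)
    if len(ys) < n_ctrl:
        return None
    # span the region: sort anchor candidates along a random direction
    phi = rng.uniform(0, np.pi)
    proj = ys * np.sin(phi) + xs * np.cos(phi)
    order = np.argsort(proj)
    picks = []
    for q in np.linspace(0.08, 0.92, n_ctrl):
        base = order[int(q * (len(order) - 1))]
        jitter = int(rng.integers(-len(order) // 20 - 1, len(order) // 20 + 1))
        idx = order[np.clip(int(q * (len(order) - 1)) + jitter, 0, len(order) - 1)]
        picks.append((ys[idx], xs[idx]))
    pts = np.array(picks, dtype=float)
    if np.hypot(*(pts[-1] - pts[0])) < 0.25 * allowed.shape[0]:
        return None
    try:
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], k=3, s=0)
    except Exception:
        return None
    t = np.linspace(0, 1, 40 * n_ctrl)
    cy, cx = interpolate.splev(t, tck)
    return np.stack([cy, cx], axis=1)


def _draw_tube(size: int, curve: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Union of disks along a curve (a bone-like tube)."""
    canvas = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    rmax = int(np.ceil(radii.max())) + 1
    for (cy, cx), r in zip(curve, radii):
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - rmax), min(size, iy + rmax + 1)
        x0, x1 = max(0, ix - rmax), min(size, ix + rmax + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        patch = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2 <= r * r
        canvas[y0:y1, x0:x1] |= patch
    return canvas


def gen_xray_leg(cfg: SynthConfig, rng: np.random.Generator) -> SamplePair:
    """X-ray-style scene: soft-tissue region with a low-contrast bone tube."""
    size = cfg.image_size
    for _ in range(_MAX_TRIES):
        center = rng.uniform(0.42 * size, 0.58 * size, size=2)
        tissue = _radial_blob_mask(rng, size, center, rng.uniform(0.32, 0.42) * size)
        r0 = max(2.0, 0.030 * size)
        allowed = ndimage.binary_erosion(tissue, iterations=int(np.ceil(r0)) + 3)
        curve = _bone_curve(rng, allowed)
        if curve is None:
            continue
        wobble = rng.uniform(0.8, 1.2) + 0.25 * np.sin(
            np.linspace(0, rng.uniform(2, 5) * np.pi, len(curve)) + rng.uniform(0, np.pi)
        )
        bone = _draw_tube(size, curve, r0 * wobble)
        if rng.random() < 0.5:  # short branch from one end
            end = curve[0] if rng.random() < 0.5 else curve[-1]
            direction = rng.uniform(-1, 1, size=2)
            direction /= np.hypot(*direction) + 1e-9
            t = np.linspace(0, rng.uniform(0.12, 0.25) * size, 60)
            branch = end[None, :] + t[:, None] * direction[None, :]
            bone |= _draw_tube(size, branch, np.full(len(branch), 0.7 * r0))
        bone &= tissue.astype(bool)
        mask = bone.astype(np.uint8)
        frac = mask.mean()
        if not (FG_FRACTION_BOUNDS[0] <= frac <= 0.2):
            continue
        tissue_soft = ndimage.gaussian_filter(tissue.astype(np.float32), 2.0)
        bone_soft = ndimage.gaussian_filter(mask.astype(np.float32), 1.0)
        img = (
            0.03
            + 0.04 * _smooth_noise(rng, size, sigma=size / 6)
            + tissue_soft * (0.27 + 0.06 * _smooth_noise(rng, size, sigma=size / 10))
            + cfg.contrast * bone_soft
        )
        if cfg.noise_sigma > 0:
            img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        image = np.repeat(img[:, :, None], 3, axis=2)
        return SamplePair(image, mask, {"mode": "xray", "fg_fraction": float(frac),
                                        "bone_radius": float(r0)})
    raise RuntimeError("could not generate an xray scene within bounds")


def gen_pair(cfg: SynthConfig, rng: np.random.Generator) -> SamplePair:
    return gen_blob_scene(cfg, rng) if cfg.mode == "blob" else gen_xray_leg(cfg, rng)


def gen_pairs(cfg: SynthConfig) -> list[SamplePair]:
    """All pairs for a config, each from an independent child seed."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_images)
    return [gen_pair(cfg, np.random.default_rng(s)) for s in seeds]


def gen_dataset(cfg: SynthConfig, out_dir: str | Path) -> Path:
    """Write n_images paired PNGs plus a JSON manifest; fully seed-determined."""
    root = Path(out_dir)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "images": []}
    for i, pair in enumerate(gen_pairs(cfg)):
        stem = f"{i:03d}"
        img8 = (pair.image * 255.0).round().astype(np.uint8)
        Image.fromarray(img8, mode="RGB").save(root / "images" / f"{stem}.png")
        Image.fromarray(pair.mask * 255, mode="L").save(root / "masks" / f"{stem}.png")
        manifest["images"].append({"stem": stem, **pair.meta})
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return root
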