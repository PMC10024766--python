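"""Dataset directories, saliency-map PNGs, checkpoints and logs.

Datasets follow the ``images/`` + ``masks/`` convention with pairing by
filename stem (the layout of the common saliency benchmarks and of
:func:`litesal.synthetic.gen_dataset`).  Images are resized to 224x224
bilinearly on access and scaled to [0, 1]; masks are nearest-neighbour
resized and binarized at 128.  Alpha channels are dropped and grayscale
inputs replicated to three channels.  Checkpoints are single ``.npz``
archives holding every weight plus the JSON-encoded model config and seed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .config import ModelConfig
from .refine import SaliencyNet

INPUT_SIZE = 224


@dataclass
class DatasetIndex:
    """Stem-matched (image, mask) file pairs under one root."""

    root: Path
    pairs: list[tuple[str, Path, Path]]
    unmatched: list[str]

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> tuple[np.ndarray, np.ndarray, str]:
        stem, img_path, mask_path = self.pairs[i]
        return load_image(img_path), load_mask(mask_path), stem

    def load_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Whole dataset as (N,3,224,224) float32 and (N,224,224) {0,1}."""
        images = np.stack([self[i][0] for i in range(len(self))])
        masks = np.stack([self[i][1] for i in range(len(self))])
        return images, masks, [p[0] for p in self.pairs]


def load_dataset_dir(root: str | Path) -> DatasetIndex:
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    for d in (img_dir, mask_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"missing dataset subdirectory {d}")
    exts = {".png", ".jpg", ".jpeg"}
    imgs = {f.stem: f for f in sorted(img_dir.iterdir()) if f.suffix.lower() in exts}
    masks = {f.stem: f for f in sorted(mask_dir.iterdir()) if f.suffix.lower() in exts}
    unmatched = sorted(set(imgs) ^ set(masks))
    if unmatched:
        warnings.warn(f"unmatched stems excluded: {unmatched}")
    pairs = [(s, imgs[s], masks[s]) for s in sorted(set(imgs) & set(masks))]
    return DatasetIndex(root=root, pairs=pairs, unmatched=unmatched)


def load_image(path: str | Path, size: int = INPUT_SIZE) -> np.ndarray:
    """RGB float32 (3, size, size) in [0, 1]; bilinear resize."""
    img = Image.open(path).convert("RGB")
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_mask(path: str | Path, size: int = INPUT_SIZE) -> np.ndarray:
    """Binary uint8 (size, size); nearest resize then threshold at 128."""
    img = Image.open(path).convert("L")
    if img.size != (size, size):
        img = img.resize((size, size), Image.NEAREST)
    return (np.asarray(img) >= 128).astype(np.uint8)


def save_saliency_map(m: np.ndarray, path: str | Path) -> Path:
    """Probability map in [0,1] -> 8-bit grayscale PNG (value = round(255 p))."""
    m = np.asarray(m, dtype=np.float64)
    m = np.squeeze(m)
    if m.ndim != 2:
        raise ValueError("saliency map must be 2-D")
    if m.min() < 0 or m.max() > 1:
        raise ValueError("saliency map must lie in [0, 1]")
    path = Path(path)
    Image.fromarray(np.round(m * 255.0).astype(np.uint8), mode="L").save(path)
    return path


def load_saliency_map(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: SaliencyNet) -> Path:
    path = Path(path)
    meta = json.dumps({"config": model.cfg.to_dict(), "format": 1})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **model.state_dict())
    return path


def load_checkpoint(path: str | Path) -> SaliencyNet:
    with np.load(Path(path)) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = SaliencyNet(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# logs
# ---------------------------------------------------------------------------

def write_train_log(out_dir: str | Path, log) -> None:
    out = Path(out_dir)
    rows = log.to_rows()
    with open(out / "train_log.json", "w") as fh:
        json.dump({"epochs": rows, "checkpoint": log.checkpoint}, fh, indent=1)
    if rows:
        with open(out / "train_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
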