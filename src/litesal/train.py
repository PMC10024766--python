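"""Training loop: Adam + per-epoch cosine annealing + paired random flips.

The published recipe fixes the optimizer (Adam, initial learning rate
3e-4), the schedule (cosine annealing) and the epoch count (60); it does
not state the loss, so the default here is plain binary cross-entropy
applied to both the coarse and the refined map with equal weights (a hybrid
BCE+IoU variant is available behind ``TrainConfig.hybrid_iou``).  Given a
seed, the whole loop — initialization, data order, flips, updates — is
deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import TrainConfig
from .nn import Tensor, binary_cross_entropy
from .refine import SaliencyNet


@dataclass
class TrainLog:
    epochs: list[dict] = field(default_factory=list)
    checkpoint: str | None = None

    def append(self, epoch: int, lr: float, mean_loss: float, train_mae: float) -> None:
        self.epochs.append(
            {"epoch": epoch, "lr": lr, "mean_loss": mean_loss, "train_mae": train_mae}
        )

    def to_rows(self) -> list[dict]:
        return list(self.epochs)


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """lr0 * 0.5 * (1 + cos(pi * epoch / epochs)); lr(0) = lr0, floor 0."""
    if not (0 <= epoch <= cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return cfg.lr0 * 0.5 * (1.0 + float(np.cos(np.pi * epoch / cfg.epochs)))


def augment_flip(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator, flip_prob: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontally mirror image and mask together with probability flip_prob."""
    if image.shape[-1] != mask.shape[-1]:
        raise ValueError("image/mask width mismatch")
    if rng.random() < flip_prob:
        return image[..., ::-1].copy(), mask[..., ::-1].copy()
    return image, mask


def _soft_iou_loss(p: Tensor, y: np.ndarray) -> Tensor:
    inter = nn.tsum(p * Tensor(y))
    union = nn.tsum(p) + float(y.sum()) - inter
    return 1.0 - inter * (union + 1e-7) ** -1.0


def loss_fn(coarse: Tensor, refine: Tensor, y: np.ndarray, cfg: TrainConfig) -> Tensor:
    """Weighted BCE over the coarse and refined probability maps."""
    yb = np.asarray(y, dtype=np.float32)
    if yb.ndim == 3:
        yb = yb[:, None]
    if coarse.shape != refine.shape or coarse.shape != yb.shape:
        raise ValueError("loss inputs must share one shape")
    wc, wr = cfg.loss_weights
    loss = wc * binary_cross_entropy(coarse, yb) + wr * binary_cross_entropy(refine, yb)
    if cfg.hybrid_iou:
        loss = loss + wr * _soft_iou_loss(refine, yb)
    return loss


def train_loop(
    model: SaliencyNet,
    images: np.ndarray,
    masks: np.ndarray,
    cfg: TrainConfig,
    out_dir: str | Path | None = None,
    max_steps: int | None = None,
    target_mae: float | None = None,
) -> tuple[dict, TrainLog]:
    """Fit `model` on an in-memory dataset (N,3,H,W float32 / N,H,W {0,1}).

    Runs ``cfg.epochs`` epochs of Adam with the cosine schedule stepped per
    epoch and paired horizontal flips.  ``max_steps`` caps the total number
    of optimizer steps and ``target_mae`` stops early once the training-set
    MAE (checked at epoch end) drops below it.  Returns the final weights
    as a state dict plus the per-epoch log; with `out_dir`, also writes the
    checkpoint and CSV/JSON logs.
    """
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.lr0)
    log = TrainLog()
    model.train()
    steps_done = 0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.empty((len(idx),) + images.shape[1:], dtype=np.float32)
            yb = np.empty((len(idx),) + masks.shape[1:], dtype=np.float32)
            for row, i in enumerate(idx):
                xb[row], yb[row] = augment_flip(images[i], masks[i], rng, cfg.flip_prob)
            coarse, refine = model(Tensor(xb))
            loss = loss_fn(coarse, refine, yb[:, None], cfg)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        mae = evaluate_train_mae(model, images, masks, cfg.batch_size)
        log.append(epoch, lr, float(np.mean(losses)), mae)
        if max_steps is not None and steps_done >= max_steps:
            break
        if target_mae is not None and mae < target_mae:
            break
    state = model.state_dict()
    if out_dir is not None:
        from .data import save_checkpoint, write_train_log

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt = out / "checkpoint.npz"
        save_checkpoint(ckpt, model)
        log.checkpoint = str(ckpt)
        write_train_log(out, log)
    return state, log


def evaluate_train_mae(
    model: SaliencyNet, images: np.ndarray, masks: np.ndarray, batch_size: int = 8
) -> float:
    """Mean absolute error of the refined map over a dataset (eval mode)."""
    was_training = model.training
    model.eval()
    errs = []
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            xb = images[start : start + batch_size]
            yb = masks[start : start + batch_size]
            _, refine = model(Tensor(xb))
            errs.append(np.abs(refine.data[:, 0] - yb).mean(axis=(1, 2)))
    if was_training:
        model.train()
    return float(np.concatenate(errs).mean())
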