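"""Saliency evaluation: MAE, threshold-swept F-measure, weighted F-measure.

MAE is the mean absolute pixel difference between a prediction in [0, 1]
and a binary ground truth.  The F-measure combines precision and recall as

    F = (1 + beta^2) * P * R / (beta^2 * P + R)

with beta^2 = 0.3 by default (the convention of the saliency literature;
some papers print 0.03 — reachable through ``MetricConfig.beta2_f``), and
is reported as the maximum over evenly spaced binarization thresholds
(strict ``p > t``, so an inverted prediction scores zero at every level).

The weighted F-measure (Margolin et al.'s protocol) corrects the
interpolation, dependency and equal-importance flaws of the plain measure:
the error map E = |p - y| is (a) substituted, on the background, by the
error at the nearest foreground pixel, (b) smoothed with a 7x7 Gaussian
(sigma 5) and kept only where it lowers the foreground error, and (c)
down-weighted on the background by 2 - exp(alpha * Delta), alpha =
ln(0.5)/5, with Delta the Euclidean distance to the nearest foreground
pixel.  Weighted precision/recall then combine with beta^2 = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .config import MetricConfig

__all__ = [
    "mae",
    "f_measure",
    "max_f_measure",
    "adaptive_f_measure",
    "weighted_fbeta",
    "evaluate_dataset",
    "table_average",
    "MetricReport",
]

_EPS = 1e-12


def _check_pair(p: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs mask {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("ground-truth mask must be binary")
    return p, y.astype(bool)


def mae(p: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute per-pixel error."""
    p, yb = _check_pair(p, y)
    return float(np.abs(p - yb).mean())


def f_measure(precision: float, recall: float, beta2: float = 0.3) -> float:
    """(1+b2)*P*R / (b2*P + R); 0 when the denominator vanishes."""
    if beta2 <= 0:
        raise ValueError("beta2 must be positive")
    den = beta2 * precision + recall
    if den <= 0:
        return 0.0
    return (1.0 + beta2) * precision * recall / den


def _threshold_counts(p: np.ndarray, yb: np.ndarray, thresholds: np.ndarray):
    """#predicted and #true-positive pixels at each threshold (strictly p > t)."""
    ps = np.sort(p, axis=None)
    ts = np.sort(p[yb], axis=None)
    pred = ps.size - np.searchsorted(ps, thresholds, side="right")
    tp = ts.size - np.searchsorted(ts, thresholds, side="right")
    return pred, tp


def max_f_measure(p: np.ndarray, y: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Maximum F over ``n_thresholds`` evenly spaced binarization levels."""
    cfg = cfg or MetricConfig()
    p, yb = _check_pair(p, y)
    n_fg = int(yb.sum())
    if n_fg == 0:
        raise ValueError("undefined recall: ground truth has no foreground")
    thresholds = np.linspace(0.0, 1.0, cfg.n_thresholds)
    pred, tp = _threshold_counts(p, yb, thresholds)
    best = 0.0
    for k in range(len(thresholds)):
        if tp[k] == 0:
            continue
        prec = tp[k] / (pred[k] + _EPS)
        rec = tp[k] / n_fg
        best = max(best, f_measure(prec, rec, cfg.beta2_f))
    return float(best)


def adaptive_f_measure(p: np.ndarray, y: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """F at the adaptive threshold 2 * mean(p) (clipped below 1)."""
    cfg = cfg or MetricConfig()
    p, yb = _check_pair(p, y)
    n_fg = int(yb.sum())
    if n_fg == 0:
        raise ValueError("undefined recall: ground truth has no foreground")
    t = min(2.0 * p.mean(), 1.0 - _EPS)
    pred = p > t
    tp = int((pred & yb).sum())
    if tp == 0:
        return 0.0
    return f_measure(tp / pred.sum(), tp / n_fg, cfg.beta2_f)


def _dependency_kernel(sigma: float, size: int = 7) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def weighted_fbeta(p: np.ndarray, y: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Weighted F-measure with dependency smoothing and distance discounting."""
    cfg = cfg or MetricConfig()
    p, yb = _check_pair(p, y)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("prediction must lie in [0, 1]")
    n_fg = int(yb.sum())
    if n_fg == 0:
        raise ValueError("undefined recall: ground truth has no foreground")

    E = np.abs(p - yb.astype(np.float64))
    dist, (iy, ix) = ndimage.distance_transform_edt(~yb, return_indices=True)
    Et = E.copy()
    Et[~yb] = E[iy[~yb], ix[~yb]]  # background error inherits nearest-foreground error
    EA = ndimage.correlate(Et, _dependency_kernel(cfg.sigma_w), mode="constant")
    min_E_EA = E.copy()
    sel = yb & (EA < E)
    min_E_EA[sel] = EA[sel]
    B = np.where(yb, 1.0, 2.0 - np.exp(cfg.alpha_w * dist))
    Ew = min_E_EA * B

    tp_w = n_fg - Ew[yb].sum()
    fp_w = Ew[~yb].sum()
    recall_w = 1.0 - Ew[yb].mean()
    precision_w = tp_w / (tp_w + fp_w + _EPS)
    return float(f_measure(precision_w, recall_w, cfg.beta2_w))


# ---------------------------------------------------------------------------
# dataset-level harness
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    per_image: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_image": self.per_image,
            "aggregate": self.aggregate,
            "unmatched": self.unmatched,
        }


def _load_gray(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0


def load_binary_mask(path: Path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Grayscale PNG -> {0,1}: values >= 128 are foreground.

    With `size` (h, w) the mask is nearest-neighbour resized first, so a
    ground truth stored at native resolution can score a 224x224 prediction.
    """
    img = Image.open(path).convert("L")
    if size is not None and img.size != (size[1], size[0]):
        img = img.resize((size[1], size[0]), Image.NEAREST)
    return (np.asarray(img) >= 128).astype(np.uint8)


def evaluate_dataset(
    pred_dir: str | Path, mask_dir: str | Path, cfg: MetricConfig | None = None
) -> MetricReport:
    """Score every prediction/mask pair matched by filename stem."""
    cfg = cfg or MetricConfig()
    pred_dir, mask_dir = Path(pred_dir), Path(mask_dir)
    preds = {f.stem: f for f in sorted(pred_dir.iterdir()) if f.suffix.lower() == ".png"}
    masks = {f.stem: f for f in sorted(mask_dir.iterdir()) if f.suffix.lower() == ".png"}
    report = MetricReport()
    report.unmatched = sorted(set(preds) ^ set(masks))
    if report.unmatched:
        warnings.warn(f"unmatched stems excluded: {report.unmatched}")
    f_fn = adaptive_f_measure if cfg.adaptive_threshold else max_f_measure
    for stem in sorted(set(preds) & set(masks)):
        p = _load_gray(preds[stem])
        y = load_binary_mask(masks[stem], size=p.shape)
        report.per_image.append(
            {
                "id": stem,
                "fbeta_max": f_fn(p, y, cfg),
                "f_weighted": weighted_fbeta(p, y, cfg),
                "mae": mae(p, y),
            }
        )
    if report.per_image:
        for key in ("fbeta_max", "f_weighted", "mae"):
            report.aggregate[key] = float(np.mean([r[key] for r in report.per_image]))
    return report


def table_average(values: list[float]) -> float:
    """Arithmetic mean reported to 3 decimals (benchmark-table convention)."""
    if len(values) == 0:
        raise ValueError("empty list")
    return round(float(np.mean(values)), 3)
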