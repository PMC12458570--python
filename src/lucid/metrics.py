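"""Segmentation evaluation metrics for comparing CAM masks to ground truth.

Pixelwise overlap metrics (IoU, Dice, accuracy, sensitivity, specificity),
rank-based AUROC of a continuous map against pixel labels, and two boundary
distances: the symmetric Hausdorff distance (max of directed max-min boundary
distances) and the mean absolute boundary deviation (mean, over predicted
boundary pixels, of the distance to the nearest truth boundary pixel).

Conventions for degenerate inputs are explicit: IoU and Dice are 1 when both
masks are empty (perfect agreement on "nothing"); the boundary distances are
undefined on empty masks and raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricReport",
    "confusion_metrics",
    "auroc_from_map",
    "hausdorff",
    "mean_abs_deviation",
    "evaluate_mask",
]

# 8-connected structuring element for boundary extraction
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MetricReport:
    iou: float
    dsc: float
    acc: float
    sen: float
    spe: float
    auroc: float | None
    hd: float | None
    mad: float | None


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Pixelwise IoU, Dice, accuracy, sensitivity and specificity."""
    pred, truth = _check_pair(pred, truth)
    tp = float(np.sum(pred & truth))
    tn = float(np.sum(~pred & ~truth))
    fp = float(np.sum(pred & ~truth))
    fn = float(np.sum(~pred & truth))
    union = tp + fp + fn
    return {
        "iou": tp / union if union > 0 else 1.0,
        "dsc": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 1.0,
        "acc": (tp + tn) / pred.size,
        "sen": tp / (tp + fn) if (tp + fn) > 0 else 1.0,
        "spe": tn / (tn + fp) if (tn + fp) > 0 else 1.0,
    }


def auroc_from_map(values: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUROC of continuous map values against pixel labels."""
    values = np.asarray(values, dtype=np.float64)
    truth = np.asarray(truth).astype(bool)
    if values.shape != truth.shape:
        raise ValueError(f"shape mismatch: {values.shape} vs {truth.shape}")
    labels = truth.ravel()
    if labels.all() or not labels.any():
        raise ValueError("AUROC undefined: truth contains a single class")
    return float(roc_auc_score(labels, values.ravel()))


def _boundary(mask: np.ndarray) -> np.ndarray:
    """8-connected boundary: mask minus its erosion."""
    return mask & ~binary_erosion(mask, structure=_STRUCT8, border_value=0)


def _boundary_coords(mask: np.ndarray, name: str) -> np.ndarray:
    if not mask.any():
        raise ValueError(f"{name} mask is empty: boundary distance undefined")
    return np.argwhere(_boundary(mask)).astype(float)


def hausdorff(pred: np.ndarray, truth: np.ndarray) -> float:
    """Symmetric Hausdorff distance between boundary pixel sets (Euclidean)."""
    pred, truth = _check_pair(pred, truth)
    a = _boundary_coords(pred, "pred")
    b = _boundary_coords(truth, "truth")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def mean_abs_deviation(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean distance from each predicted boundary pixel to the nearest truth
    boundary pixel (directed mean boundary deviation)."""
    pred, truth = _check_pair(pred, truth)
    a = _boundary_coords(pred, "pred")
    b = _boundary_coords(truth, "truth")
    return float(cKDTree(b).query(a)[0].mean())


def evaluate_mask(
    pred: np.ndarray, truth: np.ndarray, map_values: np.ndarray | None = None
) -> MetricReport:
    """Full metric report for one predicted mask (and optionally its map)."""
    conf = confusion_metrics(pred, truth)
    auroc = None
    if map_values is not None:
        try:
            auroc = auroc_from_map(map_values, truth)
        except ValueError:
            auroc = None
    hd = mad = None
    if np.asarray(pred).any() and np.asarray(truth).any():
        hd = hausdorff(pred, truth)
        mad = mean_abs_deviation(pred, truth)
    return MetricReport(auroc=auroc, hd=hd, mad=mad, **conf)
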