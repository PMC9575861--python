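"""Binary segmentation metrics: Dice, Jaccard, mean IoU, and pixelwise mAP.

mIoU is the mean of the foreground and background intersection-over-union
of a binarized prediction/label pair.  The mean average precision is
defined here as the two-class pixelwise average precision (foreground AP on
the probability map, background AP on its complement, averaged); reported
percentages based on it are therefore comparable only between runs of this
package, not across publications that may define mAP differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "MetricsReport",
    "dice_coefficient",
    "jaccard_index",
    "mean_iou",
    "mean_average_precision",
    "evaluate_pair",
    "evaluate_set",
]


@dataclass
class MetricsReport:
    """Dataset-level metric summary; values are fractions in [0, 1]."""

    miou: float
    map: float
    dice: float
    jaccard: float
    n_samples: int

    def as_percentages(self) -> dict:
        d = asdict(self)
        return {k: (round(v * 100.0, 2) if k != "n_samples" else v) for k, v in d.items()}


def _masks(pred_mask, label):
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(label).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice_coefficient(pred_mask: np.ndarray, label: np.ndarray) -> float:
    """``2|A∩B| / (|A| + |B|)``; 1 when both masks are empty."""
    a, b = _masks(pred_mask, label)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jaccard_index(pred_mask: np.ndarray, label: np.ndarray) -> float:
    """``|A∩B| / |A∪B|``; 1 when both masks are empty."""
    a, b = _masks(pred_mask, label)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def mean_iou(pred_mask: np.ndarray, label: np.ndarray) -> float:
    """Mean of foreground IoU and background IoU of the binary pair."""
    a, b = _masks(pred_mask, label)
    return 0.5 * (jaccard_index(a, b) + jaccard_index(~a, ~b))


def mean_average_precision(pred: np.ndarray, label: np.ndarray) -> float:
    """Two-class pixelwise average precision.

    Foreground AP is computed on the probability map against the label,
    background AP on the complemented pair; classes without any positive
    pixel are excluded with a warning.
    """
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label).astype(int)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {label.shape}")
    aps = []
    for name, y, s in (("foreground", label.ravel(), pred.ravel()),
                       ("background", 1 - label.ravel(), 1.0 - pred.ravel())):
        if y.sum() == 0:
            warnings.warn(f"{name} class has no positive pixels; excluded from mAP",
                          stacklevel=2)
            continue
        aps.append(float(average_precision_score(y, s)))
    if not aps:
        raise ValueError("neither class has positive pixels")
    return float(np.mean(aps))


def evaluate_pair(pred: np.ndarray, label: np.ndarray) -> MetricsReport:
    """All four metrics for one probability map / label pair
    (the mask metrics binarize the prediction at 0.5)."""
    pred = np.asarray(pred, dtype=np.float64)
    m = pred >= 0.5
    return MetricsReport(
        miou=mean_iou(m, label),
        map=mean_average_precision(pred, label),
        dice=dice_coefficient(m, label),
        jaccard=jaccard_index(m, label),
        n_samples=1,
    )


def evaluate_set(preds, labels) -> MetricsReport:
    """Unweighted mean of per-sample metrics over a dataset."""
    preds, labels = list(preds), list(labels)
    if len(preds) != len(labels) or not preds:
        raise ValueError("need equal-length non-empty lists")
    reports = [evaluate_pair(p, y) for p, y in zip(preds, labels)]
    return MetricsReport(
        miou=float(np.mean([r.miou for r in reports])),
        map=float(np.mean([r.map for r in reports])),
        dice=float(np.mean([r.dice for r in reports])),
        jaccard=float(np.mean([r.jaccard for r in reports])),
        n_samples=len(reports),
    )
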