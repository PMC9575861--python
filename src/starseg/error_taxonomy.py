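"""Pixelwise classification of segmentation errors into four categories.

False negatives (label foreground predicted background) split into *edge*
false negatives (under-segmentation at the lesion rim) and *internal hole*
false negatives (regions enclosed by correctly predicted foreground); false
positives split into *edge* false positives (over-segmentation touching the
lesion) and *external island* false positives (spurious components disjoint
from it).  The FN split uses the outward-ray PsN discriminator; an
independent connected-component classifier is provided as a cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import lesion_center, psn

__all__ = [
    "CATEGORIES",
    "CORRECT",
    "EDGE_FN",
    "INTERNAL_HOLE_FN",
    "EDGE_FP",
    "EXTERNAL_ISLAND_FP",
    "classify_errors",
    "component_fn_oracle",
    "error_summary",
]

CORRECT = 0
EDGE_FN = 1
INTERNAL_HOLE_FN = 2
EDGE_FP = 3
EXTERNAL_ISLAND_FP = 4

CATEGORIES = {
    CORRECT: "correct",
    EDGE_FN: "edge_fn",
    INTERNAL_HOLE_FN: "internal_hole_fn",
    EDGE_FP: "edge_fp",
    EXTERNAL_ISLAND_FP: "external_island_fp",
}

_EIGHT = np.ones((3, 3), dtype=bool)


def _check(pred, label):
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label).astype(bool)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs label {label.shape}")
    if not label.any():
        raise ValueError("label has no foreground")
    return pred, label


def classify_errors(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Error map over {correct, edge_fn, internal_hole_fn, edge_fp,
    external_island_fp}.

    FN pixels are split by the sign of PsN at the pixel (>= 0 internal
    hole, < 0 edge; the degenerate pixel at the center counts as internal
    hole).  FP pixels are split per 8-connected component: components
    8-adjacent to the true foreground are edge FPs, detached components are
    external islands.
    """
    pred, label = _check(pred, label)
    pred_fg = pred >= 0.5
    out = np.zeros(label.shape, dtype=np.uint8)
    c = lesion_center(label)

    fn = label & ~pred_fg
    for q in zip(*np.nonzero(fn)):
        q = (int(q[0]), int(q[1]))
        if q == c:
            out[q] = INTERNAL_HOLE_FN
        else:
            out[q] = INTERNAL_HOLE_FN if psn(q, c, pred).value >= 0 else EDGE_FN

    fp = pred_fg & ~label
    labels, n = ndimage.label(fp, structure=_EIGHT)
    near_lesion = ndimage.binary_dilation(label, structure=_EIGHT)
    for k in range(1, n + 1):
        comp = labels == k
        out[comp] = EDGE_FP if (comp & near_lesion).any() else EXTERNAL_ISLAND_FP
    return out


def component_fn_oracle(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Connected-component FN classifier, independent of PsN.

    An FN pixel is predicted background; it belongs to an internal hole
    exactly when its predicted-background component does not reach the image
    border, i.e. the region is fully enclosed by predicted foreground.
    Returns an error map whose non-zero entries are restricted to FN pixels.
    """
    pred, label = _check(pred, label)
    pred_bg = pred < 0.5
    fn = label & pred_bg
    bg_labels, _ = ndimage.label(pred_bg, structure=_EIGHT)
    border = np.zeros(label.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside_ids = np.unique(bg_labels[border & pred_bg])
    enclosed = fn & ~np.isin(bg_labels, outside_ids)
    out = np.zeros(label.shape, dtype=np.uint8)
    out[fn] = EDGE_FN
    out[enclosed] = INTERNAL_HOLE_FN
    return out


def error_summary(error_map: np.ndarray) -> dict:
    """Pixel counts and area fractions per category; fractions sum to 1."""
    error_map = np.asarray(error_map)
    n = error_map.size
    counts = {name: int((error_map == code).sum()) for code, name in CATEGORIES.items()}
    fractions = {name: counts[name] / n for name in counts}
    return {"n_pixels": n, "counts": counts, "fractions": fractions}
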