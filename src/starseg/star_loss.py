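"""Star-shape-prior loss functions for binary lesion segmentation.

The combined objective is

    L(X, Y; theta) = alpha * L_base + beta * L_sh

where ``L_base`` is an ordinary segmentation loss (pixelwise cross-entropy
or soft Dice) and ``L_sh`` is a star-shape regularization term that
penalizes predictions violating star convexity of the lesion about its
center ``c``.  For each pixel ``p`` of the pixel space and each pixel ``q``
on the digital segment from ``p`` toward ``c`` (center excluded), the
segmented variant contributes

    mu  * A * B / |qc|   if y_p = 1, P_p < 0.5 and PsN(q) <  0   (edge FN)
    rho * A * B / |qc|   if y_p = 1, P_p < 0.5 and PsN(q) >= 0   (internal hole)
    A * B * C            otherwise

with ``A = [y_p == y_q]``, ``B = |y_p - P_p|``, ``C = |P_p - P_q|``,
``|qc|`` the Euclidean distance from ``q`` to the center, and the total
divided by the number of pixels (batch averaging is done by
:func:`combined_loss`).  ``PsN`` is the outward-ray internal-hole
discriminator of :mod:`starseg.geometry`.  The ``unsegmented`` variant is
the single-branch form ``A * B * C`` for every pair; the ``non_scaled``
ablation drops the ``1/|qc|`` factor from the first two branches.

Implementation notes: the (p, q) pair lists, center distances and outward
ray tables depend only on the label, so they are computed once per label
and cached; evaluating a loss or its gradient for a new prediction is then
fully vectorized.  Gradients treat the branch selection, ``A``, ``PsN`` and
the center as constants of the current prediction (piecewise-smooth
subgradients, with ``sign(0) = 0`` at ties).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import lesion_center, outward_ray, segment_pixels_toward_center

__all__ = [
    "LossConfig",
    "LossBreakdown",
    "ShapeBreakdown",
    "cross_entropy_loss",
    "cross_entropy_grad",
    "dice_loss",
    "dice_grad",
    "star_shape_loss",
    "star_shape_loss_unsegmented",
    "star_shape_loss_non_scaled",
    "shape_loss_grad",
    "combined_loss",
    "combined_grad",
]

CE_EPS = 1e-7
DICE_SMOOTH = 1.0

Variant = Literal["none", "unsegmented", "non_scaled", "segmented"]


@dataclass
class LossConfig:
    """Weights and variant selection for the combined objective.

    Defaults are the best-performing ablation setting: Dice base loss with
    ``alpha=1, beta=0.33, mu=0.1, rho=1``.
    """

    alpha: float = 1.0
    beta: float = 0.33
    mu: float = 0.1
    rho: float = 1.0
    base: Literal["cross_entropy", "dice"] = "dice"
    variant: Variant = "segmented"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "mu", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base not in ("cross_entropy", "dice"):
            raise ValueError(f"unknown base loss {self.base!r}")
        if self.variant not in ("none", "unsegmented", "non_scaled", "segmented"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ShapeBreakdown:
    """Shape term of one sample with its per-branch subtotals."""

    shape_term: float
    edge_fn: float
    internal_hole: float
    other: float


@dataclass
class LossBreakdown:
    """Batch-level decomposition of the combined objective."""

    total: float
    base_term: float
    shape_term: float
    per_branch: dict[str, float] = field(default_factory=dict)


def _check_pair(pred: np.ndarray, label: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label, dtype=np.float64)
    if pred.shape != label.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs label {label.shape}")
    return pred, label


# ---------------------------------------------------------------------------
# base losses


def cross_entropy_loss(pred: np.ndarray, label: np.ndarray) -> float:
    """Mean pixelwise binary cross-entropy, probabilities clipped to
    ``[CE_EPS, 1 - CE_EPS]`` before the logarithm."""
    pred, label = _check_pair(pred, label)
    p = np.clip(pred, CE_EPS, 1.0 - CE_EPS)
    return float(-np.mean(label * np.log(p) + (1.0 - label) * np.log1p(-p)))


def cross_entropy_grad(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    pred, label = _check_pair(pred, label)
    p = np.clip(pred, CE_EPS, 1.0 - CE_EPS)
    return (-label / p + (1.0 - label) / (1.0 - p)) / pred.size


def dice_loss(pred: np.ndarray, label: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice loss ``1 - (2*sum(P*y) + s) / (sum(P) + sum(y) + s)``."""
    pred, label = _check_pair(pred, label)
    num = 2.0 * float(np.sum(pred * label)) + smooth
    den = float(np.sum(pred) + np.sum(label)) + smooth
    return 1.0 - num / den


def dice_grad(pred: np.ndarray, label: np.ndarray, smooth: float = DICE_SMOOTH) -> np.ndarray:
    pred, label = _check_pair(pred, label)
    num = 2.0 * float(np.sum(pred * label)) + smooth
    den = float(np.sum(pred) + np.sum(label)) + smooth
    return -(2.0 * label * den - num) / den**2


_BASE = {"cross_entropy": (cross_entropy_loss, cross_entropy_grad),
         "dice": (dice_loss, dice_grad)}


# ---------------------------------------------------------------------------
# label-dependent structure, cached


class _StarStructure:
    """All label-dependent geometry needed to evaluate the shape term.

    ``p_idx``/``q_idx`` enumerate every (p, q) pair with q on the segment
    from p toward the center (center excluded).  The ray table gives, for
    every pixel, the flat indices of its outward-ray pixels plus the
    distances needed to evaluate PsN for any prediction in one vectorized
    pass.
    """

    def __init__(self, label: np.ndarray):
        label = np.asarray(label)
        h, w = label.shape
        self.shape = (h, w)
        self.n_pix = h * w
        self.center = lesion_center(label)
        c = self.center
        flat = lambda p: p[0] * w + p[1]
        y = label.ravel().astype(bool)

        p_idx: list[int] = []
        q_idx: list[int] = []
        inv_qc: list[float] = []
        for pr in range(h):
            for pc in range(w):
                if (pr, pc) == c:
                    continue
                for q in segment_pixels_toward_center((pr, pc), c):
                    p_idx.append(pr * w + pc)
                    q_idx.append(flat(q))
                    inv_qc.append(1.0 / math.dist(q, c))
        self.p_idx = np.asarray(p_idx, dtype=np.int64)
        self.q_idx = np.asarray(q_idx, dtype=np.int64)
        self.inv_qc = np.asarray(inv_qc, dtype=np.float64)
        self.A = (y[self.p_idx] == y[self.q_idx]).astype(np.float64)
        self.y_p = y[self.p_idx].astype(np.float64)
        self.y = y.astype(np.float64)

        # outward-ray table: rays[i, s] = flat index of step s of pixel i's
        # ray (step 0 is the pixel itself), -1 padded; the center has none.
        rays = []
        for pr in range(h):
            for pc in range(w):
                if (pr, pc) == c:
                    rays.append([(pr, pc)])
                    continue
                rays.append(outward_ray((pr, pc), c, (h, w)))
        max_len = max(len(r) for r in rays)
        ray_idx = np.full((self.n_pix, max_len), -1, dtype=np.int64)
        dist_q = np.zeros((self.n_pix, max_len))
        dist_n = np.zeros((self.n_pix, max_len))
        for i, ray in enumerate(rays):
            n = ray[-1]
            q = ray[0]
            for s, pix in enumerate(ray):
                ray_idx[i, s] = flat(pix)
                dist_q[i, s] = math.dist(pix, q)
                dist_n[i, s] = math.dist(pix, n)
        self.ray_idx = ray_idx
        self.ray_valid = ray_idx >= 0
        self.ray_dist_q = dist_q
        self.ray_dist_n = dist_n
        self.ray_last = self.ray_valid.sum(axis=1) - 1

    def psn_values(self, pred_flat: np.ndarray) -> np.ndarray:
        """PsN value for every pixel of the grid (vectorized).

        For the center pixel (no ray) the value is 0; callers never use it
        because q = c is excluded from every pair list.
        """
        safe = np.where(self.ray_valid, self.ray_idx, 0)
        fg = (pred_flat[safe] >= 0.5) & self.ray_valid
        fg[:, 0] = False  # r is strictly after q
        has = fg.any(axis=1)
        first = np.argmax(fg, axis=1)
        r_step = np.where(has, first, self.ray_last)
        rows = np.arange(self.n_pix)
        return self.ray_dist_n[rows, r_step] - self.ray_dist_q[rows, r_step]


_STRUCT_CACHE: dict[bytes, _StarStructure] = {}
_STRUCT_CACHE_MAX = 64


def _structure(label: np.ndarray) -> _StarStructure:
    label = np.asarray(label).astype(np.uint8)
    key = label.shape[0].to_bytes(4, "little") + label.tobytes()
    s = _STRUCT_CACHE.get(key)
    if s is None:
        if len(_STRUCT_CACHE) >= _STRUCT_CACHE_MAX:
            _STRUCT_CACHE.pop(next(iter(_STRUCT_CACHE)))
        s = _StarStructure(label)
        _STRUCT_CACHE[key] = s
    return s


# ---------------------------------------------------------------------------
# shape terms


def _branch_masks(st: _StarStructure, P: np.ndarray):
    """FN-branch masks at p with PsN evaluated at q, per the piecewise form."""
    fn_p = (st.y_p == 1.0) & (P[st.p_idx] < 0.5)
    psn_q = st.psn_values(P)[st.q_idx]
    m_edge = fn_p & (psn_q < 0)
    m_hole = fn_p & (psn_q >= 0)
    return m_edge, m_hole, ~fn_p


def _shape_value(pred, label, cfg: LossConfig) -> ShapeBreakdown:
    """Shape term of one sample under the configured variant.

    Empty-foreground labels yield a zero shape term (with a warning) so
    batch training never aborts on a degenerate sample.
    """
    pred, label = _check_pair(pred, label)
    if cfg.variant == "none":
        return ShapeBreakdown(0.0, 0.0, 0.0, 0.0)
    if not label.any():
        warnings.warn("label has no foreground; shape term set to 0", stacklevel=3)
        return ShapeBreakdown(0.0, 0.0, 0.0, 0.0)
    st = _structure(label)
    P = pred.ravel()
    B = np.abs(st.y_p - P[st.p_idx])
    C = np.abs(P[st.p_idx] - P[st.q_idx])
    AB = st.A * B
    if cfg.variant == "unsegmented":
        other = float((AB * C).sum()) / st.n_pix
        return ShapeBreakdown(other, 0.0, 0.0, other)
    m_edge, m_hole, m_other = _branch_masks(st, P)
    scale = st.inv_qc if cfg.variant == "segmented" else 1.0
    edge = cfg.mu * float((AB * scale)[m_edge].sum()) / st.n_pix
    hole = cfg.rho * float((AB * scale)[m_hole].sum()) / st.n_pix
    other = float((AB * C)[m_other].sum()) / st.n_pix
    return ShapeBreakdown(edge + hole + other, edge, hole, other)


def star_shape_loss(pred: np.ndarray, label: np.ndarray, cfg: LossConfig | None = None) -> ShapeBreakdown:
    """Segmented star prior shape term with per-branch subtotals."""
    cfg = cfg or LossConfig()
    if cfg.variant != "segmented":
        cfg = LossConfig(cfg.alpha, cfg.beta, cfg.mu, cfg.rho, cfg.base, "segmented")
    return _shape_value(pred, label, cfg)


def star_shape_loss_non_scaled(pred: np.ndarray, label: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Ablation of the segmented term without the 1/|qc| center-distance
    scaling on the false-negative branches."""
    cfg = cfg or LossConfig()
    cfg = LossConfig(cfg.alpha, cfg.beta, cfg.mu, cfg.rho, cfg.base, "non_scaled")
    return _shape_value(pred, label, cfg).shape_term


def star_shape_loss_unsegmented(pred: np.ndarray, label: np.ndarray) -> float:
    """Single-branch basic star prior: ``A * B * C`` over every pair,
    normalized by the pixel count for batch comparability."""
    cfg = LossConfig(variant="unsegmented")
    return _shape_value(pred, label, cfg).shape_term


def shape_loss_grad(pred: np.ndarray, label: np.ndarray, cfg: LossConfig | None = None) -> np.ndarray:
    """Gradient of the configured shape term w.r.t. the prediction.

    Branch selection, ``A``, ``PsN`` and the center are held fixed
    (detached); ``sign(0) = 0`` at the absolute-value kinks, matching the
    central finite difference there.
    """
    cfg = cfg or LossConfig()
    pred, label = _check_pair(pred, label)
    g = np.zeros_like(pred, dtype=np.float64).ravel()
    if not label.any() or cfg.variant == "none":
        return g.reshape(pred.shape)
    st = _structure(label)
    P = pred.ravel()
    Pp, Pq = P[st.p_idx], P[st.q_idx]
    sB = np.sign(Pp - st.y_p)          # d|y_p - P_p| / dP_p
    B = np.abs(st.y_p - Pp)
    sC = np.sign(Pp - Pq)
    C = np.abs(Pp - Pq)

    if cfg.variant == "unsegmented":
        m_other = np.ones(len(st.p_idx), dtype=bool)
    else:
        m_edge, m_hole, m_other = _branch_masks(st, P)
        scale = st.inv_qc if cfg.variant == "segmented" else np.ones_like(st.inv_qc)
        w = np.where(m_edge, cfg.mu, cfg.rho) * scale
        m_fn = m_edge | m_hole
        np.add.at(g, st.p_idx[m_fn], (w * st.A * sB)[m_fn])

    contrib_p = st.A * (sB * C + B * sC)
    contrib_q = st.A * B * (-sC)
    np.add.at(g, st.p_idx[m_other], contrib_p[m_other])
    np.add.at(g, st.q_idx[m_other], contrib_q[m_other])
    return (g / st.n_pix).reshape(pred.shape)


# ---------------------------------------------------------------------------
# combined objective


def combined_loss(preds, labels, cfg: LossConfig | None = None) -> LossBreakdown:
    """Batch objective ``alpha * mean(base) + beta * mean(shape term)``."""
    cfg = cfg or LossConfig()
    preds = [preds] if isinstance(preds, np.ndarray) and preds.ndim == 2 else list(preds)
    labels = [labels] if isinstance(labels, np.ndarray) and labels.ndim == 2 else list(labels)
    if len(preds) == 0:
        raise ValueError("empty batch")
    if len(preds) != len(labels):
        raise ValueError("preds and labels must have equal length")
    base_fn = _BASE[cfg.base][0]
    base = float(np.mean([base_fn(p, y) for p, y in zip(preds, labels)]))
    branches = {"edge_fn": 0.0, "internal_hole": 0.0, "other": 0.0}
    shape = 0.0
    if cfg.variant != "none":
        parts = [_shape_value(p, y, cfg) for p, y in zip(preds, labels)]
        shape = float(np.mean([b.shape_term for b in parts]))
        branches = {
            "edge_fn": float(np.mean([b.edge_fn for b in parts])),
            "internal_hole": float(np.mean([b.internal_hole for b in parts])),
            "other": float(np.mean([b.other for b in parts])),
        }
    total = cfg.alpha * base + cfg.beta * shape
    return LossBreakdown(total=total, base_term=base, shape_term=shape, per_branch=branches)


def combined_grad(pred: np.ndarray, label: np.ndarray, cfg: LossConfig | None = None) -> np.ndarray:
    """Per-sample gradient of ``alpha * base + beta * shape`` w.r.t. pred."""
    cfg = cfg or LossConfig()
    g = cfg.alpha * _BASE[cfg.base][1](pred, label)
    if cfg.variant != "none" and cfg.beta != 0.0:
        g = g + cfg.beta * shape_loss_grad(pred, label, cfg)
    return g
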