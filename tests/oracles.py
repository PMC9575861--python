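"""Independent brute-force oracles used by the test suite.

The loss oracles are literal triple loops over (sample, p, q) with the
branch guards written out; they share only the geometric primitives
(segment, PsN) with the library, and those primitives are themselves
checked against independent rasterizers (skimage.draw.line, sub-pixel ray
marching) elsewhere in the suite.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import line as sk_line

from starseg.geometry import lesion_center, psn, rasterize_segment


def skimage_segment(a, b):
    """skimage Bresenham, canonicalized to the library's direction
    convention (ties resolved from the row-major smaller endpoint)."""
    a = (int(a[0]), int(a[1]))
    b = (int(b[0]), int(b[1]))
    if b < a:
        return skimage_segment(b, a)[::-1]
    rr, cc = sk_line(a[0], a[1], b[0], b[1])
    return list(zip(rr.tolist(), cc.tolist()))


def marching_ray(q, c, grid, step: float = 0.25):
    """Outward ray by sub-pixel marching and deduplication."""
    h, w = grid
    dr, dc = q[0] - c[0], q[1] - c[1]
    norm = math.hypot(dr, dc)
    dr, dc = dr / norm, dc / norm
    out, seen = [], set()
    t = 0.0
    while True:
        r = round(q[0] + t * dr)
        col = round(q[1] + t * dc)
        if not (0 <= r < h and 0 <= col < w):
            break
        if (r, col) not in seen:
            seen.add((r, col))
            out.append((r, col))
        t += step
    return out


def shape_loss_oracle(pred: np.ndarray, label: np.ndarray, mu: float, rho: float,
                      variant: str) -> tuple[float, float, float, float]:
    """Naive evaluation of the star prior; returns
    (shape_term, edge_fn, internal_hole, other), each normalized by n_pixels."""
    label = np.asarray(label, dtype=float)
    pred = np.asarray(pred, dtype=float)
    h, w = label.shape
    c = lesion_center(label)
    edge = hole = other = 0.0
    for pr in range(h):
        for pc in range(w):
            p = (pr, pc)
            if p == c:
                continue
            y_p, P_p = label[p], pred[p]
            is_fn = (y_p == 1.0) and (P_p < 0.5)
            for q in rasterize_segment(p, c)[:-1]:
                A = 1.0 if label[p] == label[q] else 0.0
                B = abs(y_p - P_p)
                if variant == "unsegmented":
                    other += A * B * abs(P_p - pred[q])
                    continue
                if is_fn:
                    scale = 1.0 / math.dist(q, c) if variant == "segmented" else 1.0
                    if psn(q, c, pred).value < 0:
                        edge += mu * A * B * scale
                    else:
                        hole += rho * A * B * scale
                else:
                    other += A * B * abs(P_p - pred[q])
    n = h * w
    return (edge + hole + other) / n, edge / n, hole / n, other / n


def star_convex_oracle(mask: np.ndarray, center) -> bool:
    """All-pairs segment membership using the skimage rasterizer."""
    mask = np.asarray(mask).astype(bool)
    for p in zip(*np.nonzero(mask)):
        for pix in skimage_segment(p, center):
            if not mask[pix]:
                return False
    return True


def random_pair(rng: np.random.Generator, size: int = 12, fg_density: float = 0.4):
    """Random binary label (non-empty) and uniform probability map."""
    label = (rng.random((size, size)) < fg_density).astype(float)
    if not label.any():
        label[size // 2, size // 2] = 1.0
    pred = rng.random((size, size))
    return pred, label
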