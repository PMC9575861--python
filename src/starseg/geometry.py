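"""Pixel-grid geometry for the star-shape prior.

A binary lesion mask is *star convex* with respect to a center pixel ``c``
when, for every foreground pixel ``p``, every pixel on the digital segment
from ``p`` to ``c`` is also foreground.  This module provides the center
estimate, deterministic Bresenham segment/ray rasterization, the
star-convexity check, and the ``psn`` discriminator that decides whether a
false-negative pixel sits inside an internal hole of the prediction or on
an under-segmented edge.

Conventions: 0-based ``(row, col)`` coordinates, row-major, row increasing
downward.  A grid is given as ``(height, width)``.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np

Point = tuple[int, int]


class PsNResult(NamedTuple):
    """Outcome of the internal-hole discriminator for one pixel.

    ``value >= 0`` classifies the query pixel as an internal-hole false
    negative, ``value < 0`` as an edge false negative.  ``r`` is the first
    re-entry of the outward ray into predicted foreground (or the border
    hit ``n`` when the ray never re-enters).
    """

    value: float
    r: Point
    n: Point


def lesion_center(label: np.ndarray) -> Point:
    """Center pixel ``c`` of a binary lesion mask.

    The integer-rounded centroid of the foreground pixels; if that pixel is
    itself background (e.g. for a ring-shaped mask) the nearest foreground
    pixel is returned, ties broken in row-major order.

    Raises ``ValueError`` if the mask has no foreground.
    """
    label = np.asarray(label)
    rows, cols = np.nonzero(label)
    if rows.size == 0:
        raise ValueError("no lesion: mask has no foreground pixel")
    cr = int(math.floor(rows.mean() + 0.5))
    cc = int(math.floor(cols.mean() + 0.5))
    if label[cr, cc]:
        return (cr, cc)
    d2 = (rows.astype(np.int64) - cr) ** 2 + (cols.astype(np.int64) - cc) ** 2
    k = int(np.argmin(d2))  # np.nonzero is row-major, argmin keeps first tie
    return (int(rows[k]), int(cols[k]))


def rasterize_segment(a: Point, b: Point) -> list[Point]:
    """Bresenham rasterization of the segment from ``a`` to ``b``.

    Endpoints inclusive; consecutive pixels are 8-connected;
    ``rasterize_segment(a, a) == [a]``.  The pixel set is symmetric in the
    endpoints (midpoint ties are resolved from the row-major smaller
    endpoint, so reversing the arguments exactly reverses the path).
    """
    r0, c0 = int(a[0]), int(a[1])
    r1, c1 = int(b[0]), int(b[1])
    if (r1, c1) < (r0, c0):
        return rasterize_segment(b, a)[::-1]
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    out: list[Point] = []
    # midpoint ties step on the minor axis immediately (err >= 0)
    if dc >= dr:
        err = 2 * dr - dc
        r = r0
        for c in range(c0, c1 + sc, sc):
            out.append((r, c))
            if err >= 0:
                r += sr
                err -= 2 * dc
            err += 2 * dr
    else:
        err = 2 * dc - dr
        c = c0
        for r in range(r0, r1 + sr, sr):
            out.append((r, c))
            if err >= 0:
                c += sc
                err -= 2 * dr
            err += 2 * dc
    return out


def _border_exit(q: Point, c: Point, grid: tuple[int, int]) -> Point:
    """Point ``n`` where the ray from ``c`` through ``q`` leaves the grid."""
    h, w = grid
    dr = q[0] - c[0]
    dc = q[1] - c[1]
    t = math.inf
    if dr > 0:
        t = min(t, (h - 1 - q[0]) / dr)
    elif dr < 0:
        t = min(t, (0 - q[0]) / dr)
    if dc > 0:
        t = min(t, (w - 1 - q[1]) / dc)
    elif dc < 0:
        t = min(t, (0 - q[1]) / dc)
    nr = int(math.floor(q[0] + t * dr + 0.5))
    nc = int(math.floor(q[1] + t * dc + 0.5))
    return (min(max(nr, 0), h - 1), min(max(nc, 0), w - 1))


def outward_ray(q: Point, c: Point, grid: tuple[int, int]) -> list[Point]:
    """Pixels of the outward ray from ``q`` away from ``c`` to the border.

    The ray starts at ``q`` in direction ``q - c`` and is rasterized up to
    the border pixel ``n`` (the last element of the result).  A border pixel
    pointing outward yields ``[q]``.

    Raises ``ValueError`` when ``q == c`` (the direction is undefined).
    """
    if tuple(q) == tuple(c):
        raise ValueError("degenerate ray: q coincides with the center c")
    return rasterize_segment(tuple(q), _border_exit(tuple(q), tuple(c), grid))


def psn(q: Point, c: Point, pred: np.ndarray, grid: tuple[int, int] | None = None) -> PsNResult:
    """Internal-hole discriminator for a false-negative pixel ``q``.

    Traces the outward ray from ``q`` (direction ``q - c``) to the border
    hit ``n``.  ``r`` is the first pixel strictly after ``q`` whose predicted
    foreground probability is >= 0.5, i.e. the re-entry into predicted
    foreground; if the ray never re-enters, ``r = n``.  The returned value is

        ``|r n| - |r q|``   (Euclidean pixel distances)

    which is >= 0 exactly when the remaining run to the border is at least
    as long as the run back to ``q`` — the signature of a hole enclosed by
    predicted foreground.  A negative value marks an edge false negative.
    """
    pred = np.asarray(pred)
    if grid is None:
        grid = pred.shape
    ray = outward_ray(q, c, grid)
    n = ray[-1]
    r = n
    for pix in ray[1:]:
        if pred[pix] >= 0.5:
            r = pix
            break
    value = math.dist(r, n) - math.dist(r, q)
    return PsNResult(value=value, r=r, n=n)


def is_star_convex(mask: np.ndarray, center: Point) -> bool:
    """True iff every foreground pixel sees the center through foreground.

    Checks, for each foreground pixel ``p``, that every pixel of the
    Bresenham segment from ``p`` to ``center`` is foreground.

    Raises ``ValueError`` if ``center`` is not a foreground pixel.
    """
    mask = np.asarray(mask).astype(bool)
    center = (int(center[0]), int(center[1]))
    if not mask[center]:
        raise ValueError("center must be a foreground pixel of the mask")
    for p in zip(*np.nonzero(mask)):
        for pix in rasterize_segment((int(p[0]), int(p[1])), center):
            if not mask[pix]:
                return False
    return True


def segment_pixels_toward_center(
    p: Point, c: Point
) -> Sequence[Point]:
    """Pixels of ``rasterize_segment(p, c)`` with the center itself removed.

    This is the range of the inner summation index ``q`` of the star prior:
    ``q`` runs from ``p`` inclusive toward ``c`` exclusive, so the
    center-distance ``|qc|`` is always >= 1.  For ``p == c`` the range is
    empty.
    """
    seg = rasterize_segment(p, c)
    return seg[:-1]
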