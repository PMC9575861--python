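"""Synthetic star-shaped lesion masks and controlled prediction corruptions.

Real dermoscopy lesions are speckle shaped — star convex about a center —
and segmentation models fail on them in characteristic ways: internal
holes, external islands, and over/under-segmented rims.  This module
produces binary lesion masks that are star convex by construction, plus
probability maps with those defects injected at known pixels, so every
classifier and loss in the package can be validated against an exact
ground-truth error map without any external data.

Masks are star polygons: per-spoke radii are sampled around a mean and
linearly interpolated in angle, giving a radial function r(theta); the
radial region is rasterized and then repaired to discrete star convexity
(pixels whose Bresenham segment to the center crosses background are
dropped; this almost never fires but guarantees the invariant).

Corrupted predictions start from a soft rendering of the label (foreground
0.9, background 0.1) so the B and C factors of the shape losses are
non-degenerate, then carve hole disks well inside the lesion, add island
disks well outside it, optionally erode a rim arc, and finally add clipped
Gaussian noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .error_taxonomy import EDGE_FN, INTERNAL_HOLE_FN, EXTERNAL_ISLAND_FP
from .geometry import is_star_convex, lesion_center, outward_ray, rasterize_segment

__all__ = [
    "LesionSpec",
    "CorruptionSpec",
    "generate_lesion_mask",
    "corrupt_prediction",
    "render_image",
    "generate_samples",
    "generate_dataset",
]

RIM_BITE_DEPTH = 3  # px eroded inward from the rim by a rim bite
SOFT_FG, SOFT_BG = 0.9, 0.1


@dataclass(frozen=True)
class LesionSpec:
    """Geometry of one synthetic lesion.

    ``radius_jitter`` is the relative spread of the per-spoke radii,
    ``center_jitter`` the relative off-center displacement of the lesion
    within the image.
    """

    image_size: int = 64
    n_spokes: int = 12
    radius_mean: float = 20.0
    radius_jitter: float = 0.15
    center_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_spokes < 3:
            raise ValueError("n_spokes must be >= 3")
        max_extent = (self.radius_mean * (1 + self.radius_jitter)
                      + self.center_jitter * self.image_size / 2)
        if max_extent >= self.image_size / 2:
            raise ValueError("lesion radius does not fit inside the grid")


@dataclass(frozen=True)
class CorruptionSpec:
    """Defects injected into a soft prediction derived from a label.

    Holes are carved at least 2 px inside the lesion rim, islands placed at
    least 2 px outside it; ``rim_bite_fraction`` erodes that angular
    fraction of the rim by ``RIM_BITE_DEPTH`` pixels.
    """

    hole_count: int = 2
    hole_radius: int = 3
    island_count: int = 1
    island_radius: int = 3
    rim_bite_fraction: float = 0.0
    prob_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("hole_count", "island_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.hole_count > 0 and self.hole_radius < 1:
            raise ValueError("hole_radius must be >= 1 when holes are requested")
        if self.island_count > 0 and self.island_radius < 1:
            raise ValueError("island_radius must be >= 1 when islands are requested")
        if not 0 <= self.rim_bite_fraction < 1:
            raise ValueError("rim_bite_fraction must be in [0, 1)")
        if self.prob_noise_sd < 0:
            raise ValueError("prob_noise_sd must be >= 0")


def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return yy**2 + xx**2 <= r**2


def generate_lesion_mask(spec: LesionSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Star-convex lesion mask and its generation center.

    Returns ``(mask, center)`` with ``mask`` a boolean ``image_size`` square
    grid; ``is_star_convex(mask, center)`` holds by construction.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    half = (s - 1) / 2.0
    jit = spec.center_jitter * s / 2.0
    cr = int(round(half + rng.uniform(-jit, jit)))
    cc = int(round(half + rng.uniform(-jit, jit)))

    angles = np.linspace(0.0, 2 * np.pi, spec.n_spokes, endpoint=False)
    radii = spec.radius_mean * (1.0 + spec.radius_jitter * rng.uniform(-1, 1, spec.n_spokes))
    radii = np.maximum(radii, 2.0)

    rows, cols = np.mgrid[0:s, 0:s]
    theta = np.arctan2(rows - cr, cols - cc) % (2 * np.pi)
    rho = np.hypot(rows - cr, cols - cc)
    # linear interpolation of the radial function between adjacent spokes
    step = 2 * np.pi / spec.n_spokes
    k = np.floor(theta / step).astype(int) % spec.n_spokes
    frac = theta / step - np.floor(theta / step)
    r_theta = radii[k] * (1 - frac) + radii[(k + 1) % spec.n_spokes] * frac
    mask = rho <= r_theta
    mask[cr, cc] = True

    # repair to discrete star convexity: drop pixels whose segment to the
    # center crosses background; iterate to a fixed point (rarely > 1 pass)
    changed = True
    while changed:
        changed = False
        for p in zip(*np.nonzero(mask)):
            p = (int(p[0]), int(p[1]))
            for pix in rasterize_segment(p, (cr, cc)):
                if not mask[pix]:
                    mask[p] = False
                    changed = True
                    break
    return mask, (cr, cc)


def _angle(p, c) -> float:
    return math.atan2(p[0] - c[0], p[1] - c[1]) % (2 * math.pi)


def _in_window(angle: float, start: float, width: float) -> bool:
    return (angle - start) % (2 * math.pi) <= width


def corrupt_prediction(
    label: np.ndarray, spec: CorruptionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Soft probability map with injected defects and their ground truth.

    Returns ``(pred, defects)``; ``defects`` is an error map marking the
    injected pixels with the taxonomy codes (internal-hole FN for carved
    holes, external-island FP for added islands, edge FN for the rim bite).
    Placement keeps defects separated so each remains classifiable: holes
    sit >= 2 px inside the rim, islands >= 2 px outside, and when a rim bite
    is present, holes and islands avoid its (expanded) angular sector so no
    outward ray from one defect runs through another.

    Raises ``RuntimeError`` when a defect cannot be placed after bounded
    retries (e.g. holes larger than the lesion interior).
    """
    label = np.asarray(label).astype(bool)
    if not label.any():
        raise ValueError("label has no foreground")
    rng = np.random.default_rng(spec.seed)
    pred = np.where(label, SOFT_FG, SOFT_BG).astype(np.float64)
    defects = np.zeros(label.shape, dtype=np.uint8)
    c = lesion_center(label)
    h, w = label.shape

    bite_start = bite_width = None
    if spec.rim_bite_fraction > 0:
        bite_width = spec.rim_bite_fraction * 2 * math.pi
        bite_start = rng.uniform(0, 2 * math.pi)
        dist_in = ndimage.distance_transform_edt(label)
        ang = np.arctan2(np.arange(h)[:, None] - c[0],
                         np.arange(w)[None, :] - c[1]) % (2 * math.pi)
        in_win = (ang - bite_start) % (2 * math.pi) <= bite_width
        bite = label & in_win & (dist_in <= RIM_BITE_DEPTH)
        bite[c] = False  # keep the center intact for downstream geometry
        pred[bite] = SOFT_BG
        defects[bite] = EDGE_FN
        # extend the bite to its full radial shadow: rasterized outward rays
        # can wobble half a pixel across the angular window boundary, so any
        # remaining foreground on a bitten pixel's ray is carved too — this
        # makes every bitten pixel a true edge FN (its ray never re-enters
        # predicted foreground)
        frontier = [tuple(p) for p in np.argwhere(bite)]
        while frontier:
            new = []
            for q in frontier:
                for pix in outward_ray(q, c, label.shape)[1:]:
                    if pred[pix] >= 0.5 and label[pix]:
                        pred[pix] = SOFT_BG
                        defects[pix] = EDGE_FN
                        new.append(pix)
            frontier = new

    def clear_of_bite(center, pad) -> bool:
        if bite_start is None:
            return True
        d = max(math.dist(center, c), 1.0)
        margin = math.atan2(pad, d) + 0.2
        a = _angle(center, c)
        return not _in_window(a, (bite_start - margin) % (2 * math.pi),
                              bite_width + 2 * margin)

    disk_h = _disk(spec.hole_radius)
    allowed_holes = ndimage.binary_erosion(label, structure=_disk(spec.hole_radius + 2))
    allowed_holes[c] = False
    for _ in range(spec.hole_count):
        cand = np.argwhere(allowed_holes)
        placed = False
        for _try in range(200):
            if cand.size == 0:
                break
            hc = tuple(cand[rng.integers(len(cand))])
            if not clear_of_bite(hc, spec.hole_radius + 2):
                continue
            # keep holes >= 2 px apart so carved regions never merge and the
            # outward-ray chord through any single hole stays short
            pad2 = 2 * spec.hole_radius + 2
            box = defects[max(hc[0] - pad2, 0):hc[0] + pad2 + 1,
                          max(hc[1] - pad2, 0):hc[1] + pad2 + 1]
            if (box == INTERNAL_HOLE_FN).any():
                continue
            rr = slice(hc[0] - spec.hole_radius, hc[0] + spec.hole_radius + 1)
            cc_ = slice(hc[1] - spec.hole_radius, hc[1] + spec.hole_radius + 1)
            patch = defects[rr, cc_]
            hole = disk_h & label[rr, cc_]
            hole = hole & ~np.fromfunction(
                lambda i, j: (i + rr.start == c[0]) & (j + cc_.start == c[1]),
                hole.shape, dtype=int)
            pred[rr, cc_][hole] = SOFT_BG
            patch[hole] = INTERNAL_HOLE_FN
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place an internal hole; lesion too small")

    disk_i = _disk(spec.island_radius)
    pad = spec.island_radius + 2
    far = ~ndimage.binary_dilation(label, structure=_disk(pad))
    fits = np.zeros_like(far)
    fits[spec.island_radius:h - spec.island_radius,
         spec.island_radius:w - spec.island_radius] = True
    allowed_islands = far & fits
    for _ in range(spec.island_count):
        cand = np.argwhere(allowed_islands)
        placed = False
        for _try in range(200):
            if cand.size == 0:
                break
            ic = tuple(cand[rng.integers(len(cand))])
            if not clear_of_bite(ic, pad):
                continue
            rr = slice(ic[0] - spec.island_radius, ic[0] + spec.island_radius + 1)
            cc_ = slice(ic[1] - spec.island_radius, ic[1] + spec.island_radius + 1)
            pred[rr, cc_][disk_i] = SOFT_FG
            defects[rr, cc_][disk_i] = EXTERNAL_ISLAND_FP
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place an external island; no room outside lesion")

    if spec.prob_noise_sd > 0:
        pred = np.clip(pred + rng.normal(0.0, spec.prob_noise_sd, pred.shape), 0.0, 1.0)
    return pred, defects


def render_image(label: np.ndarray, pred: np.ndarray, seed: int = 0,
                 noise_sd: float = 0.03) -> np.ndarray:
    """Grayscale image in [0, 1] whose intensity encodes the corrupted
    prediction: dark where a naive intensity-based segmenter would see
    lesion, bright elsewhere.

    Hole defects therefore appear as bright spots inside the lesion — the
    appearance that misleads an unregularized model into predicting
    internal holes.
    """
    rng = np.random.default_rng(seed)
    img = 0.78 - 0.44 * (np.asarray(pred) >= 0.5)
    img = ndimage.gaussian_filter(img, sigma=0.8)
    img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _sample_seed(base: int, i: int, salt: int) -> int:
    return int(np.random.SeedSequence([base, i, salt]).generate_state(1)[0] % (2**31))


def generate_samples(n: int, lesion: LesionSpec, corruption: CorruptionSpec) -> list[dict]:
    """In-memory dataset of ``n`` samples with a 6:2:2 train/val/test split.

    Each sample dict has ``image`` (float grayscale), ``mask`` (bool label),
    ``prob`` (corrupted probability map), ``defects`` (injected error map),
    ``center`` and ``split``.
    """
    n_train = int(n * 0.6)
    n_val = int(n * 0.2)
    out = []
    for i in range(n):
        lspec = replace(lesion, seed=_sample_seed(lesion.seed, i, 1))
        cspec = replace(corruption, seed=_sample_seed(corruption.seed, i, 2))
        mask, center = generate_lesion_mask(lspec)
        prob, defects = corrupt_prediction(mask, cspec)
        image = render_image(mask, prob, seed=_sample_seed(corruption.seed, i, 3))
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        out.append({"image": image, "mask": mask, "prob": prob,
                    "defects": defects, "center": center, "split": split})
    return out


def generate_dataset(n: int, lesion: LesionSpec, corruption: CorruptionSpec,
                     out_dir: str | Path) -> dict:
    """Write ``n`` samples to ``out_dir`` and return the manifest.

    Per sample: an 8-bit grayscale image PNG, a 0/255 mask PNG, and a
    32-bit float probability-map TIFF; the manifest (also written as
    ``manifest.json``) records file names, the 6:2:2 split and the specs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = generate_samples(n, lesion, corruption)
    entries = []
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        img8 = (s["image"] * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / f"{stem}_image.png")
        Image.fromarray(np.where(s["mask"], 255, 0).astype(np.uint8), mode="L").save(
            out_dir / f"{stem}_mask.png")
        tifffile.imwrite(out_dir / f"{stem}_prob.tif", s["prob"].astype(np.float32))
        entries.append({
            "image": f"{stem}_image.png",
            "mask": f"{stem}_mask.png",
            "prob": f"{stem}_prob.tif",
            "split": s["split"],
        })
    manifest = {
        "n": n,
        "lesion_spec": asdict(lesion),
        "corruption_spec": asdict(corruption),
        "samples": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
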