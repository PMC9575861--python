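"""Preprocessing and the desk-scale training/ablation harness.

The harness exists to exercise the loss variants end to end: a small numpy
encoder-decoder is trained with the configured combined objective on
synthetic lesion data, and the four ablation variants (no prior,
unsegmented prior, prior without center-distance scaling, segmented prior)
are compared on identical data and seeds.  Preprocessing follows the usual
dermoscopy pipeline: aspect-preserving resize so the longer side matches
the target, symmetric padding to a square, and (in training mode only)
random flips and brightness shifts; masks are resized nearest-neighbor and
never brightness-adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import star_loss as sl
from .error_taxonomy import INTERNAL_HOLE_FN, classify_errors, error_summary
from .metrics import MetricsReport, evaluate_set
from .nn import Adam, ToySegNet

__all__ = [
    "PreprocessConfig",
    "TrainConfig",
    "preprocess",
    "augment_pair",
    "learning_rate_at",
    "train_toy",
    "predict",
    "ablate_toy",
    "format_ablation_table",
    "VARIANTS",
]

VARIANTS = ("none", "unsegmented", "non_scaled", "segmented")


@dataclass
class PreprocessConfig:
    target_side: int = 256
    pad_value: float = 0.0
    flip: bool = True
    brightness_delta: float = 0.1

    def __post_init__(self):
        if self.target_side < 32:
            raise ValueError("target_side must be >= 32")


@dataclass
class TrainConfig:
    """Optimization settings for the toy harness.

    The learning-rate schedule is step decay: the rate is multiplied by
    ``decay_factor`` every ``decay_every`` epochs.  ``freeze_epochs`` keeps
    the encoder convolutions fixed for the first epochs.

    ``prior_warmup_epochs`` trains with the base loss alone before enabling
    the shape term (``None`` means the first two thirds of the epochs).  The
    star prior is a regularizer of an already-roughly-segmenting model: its
    smoothing branch makes the trivial uniform prediction a strong attractor
    for a randomly initialized network, so — like fine-tuning a pretrained
    backbone — the prior is applied only once the base loss has shaped the
    prediction.
    """

    epochs: int = 30
    lr: float = 1e-3
    decay_every: int = 5
    decay_factor: float = 0.95
    freeze_epochs: int = 0
    prior_warmup_epochs: int | None = None
    seed: int = 0
    loss: sl.LossConfig = field(default_factory=sl.LossConfig)
    image_size: int = 64
    batch_size: int = 4

    def __post_init__(self):
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must be in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be divisible by 4 (two pooling levels)")

    @property
    def warmup(self) -> int:
        if self.prior_warmup_epochs is not None:
            return self.prior_warmup_epochs
        return (2 * self.epochs) // 3


def preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None,
               is_mask: bool = False) -> np.ndarray:
    """Resize so the longer side equals ``target_side``, pad to square.

    Masks use nearest-neighbor resampling and stay binary; images are
    linearly interpolated.  Already-square target-size inputs pass through
    unchanged (idempotence).
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    h, w = image.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    t = cfg.target_side
    if (h, w) == (t, t):
        return image.copy()
    scale = t / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    if is_mask:
        # nearest-neighbor keeps the original value set (e.g. {0, 255})
        out = resize(image, (nh, nw), order=0, anti_aliasing=False,
                     preserve_range=True).astype(image.dtype)
    else:
        out = resize(image.astype(float), (nh, nw), order=1, anti_aliasing=nh < h,
                     preserve_range=True)
    pr, pc = t - nh, t - nw
    pad = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2))
    return np.pad(out, pad, constant_values=cfg.pad_value)


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: PreprocessConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Training-mode augmentation: joint random flips, image-only
    brightness shift."""
    if cfg.flip:
        if rng.random() < 0.5:
            image, mask = image[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            image, mask = image[::-1, :], mask[::-1, :]
    if cfg.brightness_delta > 0:
        image = np.clip(image + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta), 0, 1)
    return image.copy(), mask.copy()


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    return cfg.lr * cfg.decay_factor ** (epoch // cfg.decay_every)


def _as_pairs(dataset) -> tuple[list[np.ndarray], list[np.ndarray]]:
    images, masks = [], []
    for s in dataset:
        if isinstance(s, dict):
            images.append(np.asarray(s["image"], dtype=np.float64))
            masks.append(np.asarray(s["mask"]).astype(np.float64))
        else:
            images.append(np.asarray(s[0], dtype=np.float64))
            masks.append(np.asarray(s[1]).astype(np.float64))
    return images, masks


def predict(model: ToySegNet, images) -> list[np.ndarray]:
    """Probability maps for a list of 2-D grayscale images."""
    x = np.stack([np.asarray(im, dtype=np.float64) for im in images])[:, None]
    prob, _ = model.forward(x, want_cache=False)
    return [prob[i, 0] for i in range(len(images))]


def train_toy(train_set, val_set, cfg: TrainConfig | None = None):
    """Train the toy encoder-decoder on the configured combined loss.

    ``train_set``/``val_set`` are sequences of ``(image, mask)`` pairs or
    dicts with ``image``/``mask`` keys.  Returns ``(model, log)`` where
    ``log`` has one entry per epoch with the mean training loss breakdown
    and validation metrics.  ``epochs=0`` returns the initialized model with
    its untrained validation metrics.

    Raises ``RuntimeError`` if the loss becomes non-finite.
    """
    cfg = cfg or TrainConfig()
    tr_img, tr_mask = _as_pairs(train_set)
    if not tr_img:
        raise ValueError("empty training set")
    va_img, va_mask = _as_pairs(val_set)
    rng = np.random.default_rng(cfg.seed)
    model = ToySegNet(seed=cfg.seed)
    opt = Adam(model.params, lr=cfg.lr)
    log: list[dict] = []

    def val_metrics() -> MetricsReport | None:
        if not va_img:
            return None
        return evaluate_set(predict(model, va_img), va_mask)

    if cfg.epochs == 0:
        log.append({"epoch": 0, "train_loss": None,
                    "val": val_metrics().as_percentages() if va_img else None})
        return model, log

    n = len(tr_img)
    for epoch in range(cfg.epochs):
        opt.lr = learning_rate_at(epoch, cfg)
        frozen = set(ToySegNet.ENCODER) if epoch < cfg.freeze_epochs else frozenset()
        loss_cfg = (replace(cfg.loss, beta=0.0) if epoch < cfg.warmup else cfg.loss)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs = [tr_img[i] for i in idx]
            masks = [tr_mask[i] for i in idx]
            x = np.stack(imgs)[:, None]
            prob, caches = model.forward(x)
            bk = sl.combined_loss([prob[j, 0] for j in range(len(idx))], masks, loss_cfg)
            if not math.isfinite(bk.total):
                raise RuntimeError(
                    f"loss diverged to {bk.total} at epoch {epoch}; "
                    f"base={bk.base_term} shape={bk.shape_term}")
            epoch_losses.append(bk.total)
            dprob = np.stack([
                sl.combined_grad(prob[j, 0], masks[j], loss_cfg) / len(idx)
                for j in range(len(idx))
            ])[:, None]
            grads = model.backward(dprob, caches)
            opt.step(model.params, grads, frozen=frozen)
        entry = {"epoch": epoch + 1,
                 "lr": opt.lr,
                 "train_loss": float(np.mean(epoch_losses))}
        vm = val_metrics()
        if vm is not None:
            entry["val"] = vm.as_percentages()
        log.append(entry)
    return model, log


def ablate_toy(train_set, val_set, test_set, cfg: TrainConfig | None = None,
               variants=VARIANTS) -> dict:
    """Train each loss variant on identical data/seeds; tabulate test
    metrics and residual internal-hole pixels.

    Returns ``{variant: {"miou": ..., "map": ..., "dice": ..., "jaccard": ...,
    "internal_hole_fn_px": ...}}`` with metric values as percentages.
    """
    cfg = cfg or TrainConfig()
    te_img, te_mask = _as_pairs(test_set)
    results: dict[str, dict] = {}
    for variant in variants:
        vcfg = replace(cfg, loss=replace(cfg.loss, variant=variant))
        model, _ = train_toy(train_set, val_set, vcfg)
        preds = predict(model, te_img)
        report = evaluate_set(preds, te_mask).as_percentages()
        holes = 0
        for p, y in zip(preds, te_mask):
            if y.any():
                em = classify_errors(p, y)
                holes += error_summary(em)["counts"]["internal_hole_fn"]
        results[variant] = {**{k: report[k] for k in ("miou", "map", "dice", "jaccard")},
                            "internal_hole_fn_px": holes}
    return results


def format_ablation_table(results: dict) -> str:
    """Aligned text rendering of :func:`ablate_toy` output."""
    cols = ["variant", "mIoU (%)", "mAP (%)", "Dice (%)", "Jaccard (%)", "hole px"]
    rows = [cols]
    for variant, r in results.items():
        rows.append([variant, f"{r['miou']:.2f}", f"{r['map']:.2f}",
                     f"{r['dice']:.2f}", f"{r['jaccard']:.2f}",
                     str(r["internal_hole_fn_px"])])
    widths = [max(len(row[i]) for row in rows) for i in range(len(cols))]
    lines = ["  ".join(cell.ljust(widths[i]) for i, cell in enumerate(row)) for row in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)
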