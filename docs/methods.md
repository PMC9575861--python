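# Methods

## Model

A binary lesion mask `y` on a pixel grid Ω is *star convex* about a center
`c` when, for every foreground pixel `p`, every pixel of the digital
segment from `p` to `c` is foreground. This is the anatomical model of a
speckle-shaped melanoma lesion: one compact body, arbitrary rim geometry,
no interior cavities, no satellites. The package's central object is a loss
regularizer that penalizes predicted probability maps violating this model,
together with the complementary diagnostic machinery (an error taxonomy
that names the violations, and simulators that manufacture them on demand).

### Geometry conventions

* Coordinates are 0-based `(row, col)`, row-major, row increasing downward.
* The center `c` is the integer-rounded centroid of the label foreground,
  snapped to the nearest foreground pixel (Euclidean, row-major ties) when
  the centroid falls outside the set (e.g. ring-like masks).
* Segments are rasterized with classic 8-connected Bresenham, endpoints
  inclusive. Midpoint ties are resolved from the row-major smaller
  endpoint, which makes the pixel path exactly reversal-symmetric in its
  endpoints — a property plain Bresenham lacks. The hand-written rasterizer
  is verified pixel-for-pixel against `skimage.draw.line` (an independent
  implementation) on randomized endpoint pairs within a 16×16 grid in the
  test suite, modulo that tie canonicalization.
* The outward ray of `q` w.r.t. `c` starts at `q` in direction `q − c` and
  ends at the pixel where the continuous ray exits the grid. A border pixel
  pointing outward yields the one-pixel ray `[q]`.

### The PsN discriminator

For a false-negative pixel `q` (label 1, predicted probability < 0.5), walk
the outward ray to the border hit `n`; let `r` be the first pixel strictly
after `q` with predicted probability ≥ 0.5 — the re-entry into predicted
foreground — or `n` if the ray never re-enters. Then

    PsN(q) = |rn| − |rq|     (Euclidean pixel distances).

`PsN ≥ 0` classifies `q` as an internal-hole point: the run back to `q` is
shorter than the run out to the border, the signature of a region enclosed
by predicted foreground. `PsN < 0` classifies an edge false negative; in
particular a ray with no re-entry gives `r = n` and `PsN = −|qn| < 0` for
any `q` strictly inside the border. The tie `PsN = 0` counts as internal
hole. Defining `r` as the first re-entry is a deliberate operationalization:
an internal hole is by definition surrounded by predicted foreground,
whereas an under-segmented rim has open background beyond it.

### The shape loss

With `A = [y_p = y_q]`, `B = |y_p − P_p|`, `C = |P_p − P_q|`, the segmented
shape term sums over every pixel `p` and every `q` on the segment from `p`
toward `c`:

    μ · A · B / |qc|   if y_p = 1, P_p < 0.5, PsN(q) <  0
    ρ · A · B / |qc|   if y_p = 1, P_p < 0.5, PsN(q) >= 0
    A · B · C          otherwise

normalized by the number of pixels; the batch objective is
`α·mean(base) + β·mean(shape)`. Note the guards sit at `p` while PsN is
evaluated at `q`, exactly as the piecewise definition is stated: a rim
false negative `p` therefore contributes to the internal-hole branch
through its deep-interior `q`'s (whose rays re-enter immediately). The
`1/|qc|` center-distance scaling equalizes penalties between errors near
the center (few, short segments) and near the rim (many, long segments).

Conventions that the definition leaves open, fixed here once:

* `q` runs from `p` inclusive to the center exclusive, so `|qc| ≥ 1` and
  the division is always safe; `p = c` contributes nothing.
* `*` is scalar multiplication per `(p, q)` pair — `A`, `B`, `C` are
  per-pixel scalars.
* The unsegmented variant (single branch `A·B·C` over all pairs, no guards)
  is normalized by the pixel count too, for batch comparability.
* The non-scaled ablation drops `1/|qc|` from the two FN branches only.
* Empty-foreground labels have no center; the shape term is defined as 0
  with a warning, so a degenerate batch sample never aborts training.
* Multi-component lesions use the single global snapped centroid;
  per-component centers are out of scope.
* Cross-entropy clips probabilities at 1e-7; soft Dice uses smoothing 1.

### Gradients

`shape_loss_grad` differentiates the shape term w.r.t. the prediction with
the branch selection, `A`, PsN and the center treated as constants of the
current prediction, and `sign(0) = 0` at the absolute-value kinks (the
central-difference subgradient). The FN branches contribute
`−w·A/(|qc|)` at `p`; the C branch contributes
`A·(sign(P_p−y_p)·C + B·sign(P_p−P_q))` at `p` and `A·B·sign(P_q−P_p)` at
`q`. Finite-difference agreement to 1e-4 on small fixtures is part of the
acceptance suite.

### Error taxonomy

Every pixel gets exactly one label. False negatives split by PsN at the
pixel (`≥ 0` internal hole, `< 0` edge; the degenerate pixel at `c` counts
as internal hole). False positives split per 8-connected component:
components 8-adjacent to true foreground are edge FPs, detached components
are external islands — the adjacency rule is this package's choice, since
the taxonomy names the categories only pictorially. An independent
cross-check, `component_fn_oracle`, calls an FN pixel an internal hole iff
its predicted-background connected component does not reach the image
border; on clean single-defect fixtures the two classifiers agree on 100%
of FN pixels (acceptance-tested), while pathological non-star inputs may
legitimately disagree.

### Metrics

Dice `2|A∩B|/(|A|+|B|)`, Jaccard `|A∩B|/|A∪B|` (both 1 for empty-vs-empty),
mIoU = mean of foreground and background IoU, dataset values are unweighted
means over samples. **mAP caveat**: mean average precision here is
two-class pixelwise average precision (foreground AP on `P`, background AP
on `1−P`, averaged, via scikit-learn); published dermoscopy tables rarely
state their mAP definition, so cross-paper numeric comparison of this
column is not claimed.

## Synthetic data

`generate_lesion_mask` samples `n_spokes` radii around `radius_mean`
(relative jitter `radius_jitter`), interpolates them linearly in angle to a
radial function `r(θ)`, rasterizes `ρ ≤ r(θ)`, and repairs the result to
discrete star convexity (pixels whose Bresenham segment to the center
crosses background are dropped, to a fixed point — this almost never
fires). Defaults: 64×64 grid, 12 spokes, mean radius 20, jitter 0.15,
center jitter 0.05 — a lesion filling ~30% of the frame as in cropped
dermoscopy.

`corrupt_prediction` renders the label softly (foreground 0.9, background
0.1, so the `B`/`C` factors are non-degenerate), then injects defects with
known ground truth: hole disks ≥ 2 px inside the rim and ≥ 2 px apart,
island disks ≥ 2 px outside the lesion, and optionally a rim bite (an
angular sector eroded 3 px from the rim, extended to its full radial
shadow so every bitten pixel's outward ray stays defect-or-background).
When a bite is present, holes and islands avoid its expanded angular
sector. These placement rules guarantee each defect is classifiable in
isolation — the geometric margins keep `|rn| > |rq|` for every hole pixel
and prevent one defect from shadowing another's ray — which is what makes
the pixel-exact round-trip (injected map == `classify_errors` output at
zero noise) a meaningful acceptance property. Clipped Gaussian noise
(`prob_noise_sd`) can be added on top for robustness tests.

`render_image` produces a grayscale image whose intensity encodes the
*corrupted* prediction (lesion dark at 0.34, background and hole confusers
bright at 0.78, Gaussian blur σ=0.8, noise σ=0.03): an intensity-only
segmenter reproduces exactly the injected failure modes. Holes appear as
bright in-lesion speckles — the light keratotic patches that mislead real
models. What the simulator does **not** emulate: dermoscopy texture, hair
and ruler artifacts, color, smooth lesion borders, or intensity overlap
between lesion and skin. Passing tests therefore validate the loss and
taxonomy machinery, not clinical segmentation accuracy.

`generate_dataset` writes image/mask/probability triples with a 6:2:2
train/val/test split, fully determined by seeds.

## Training harness

The paper-scale experiment (pretrained ResNet34-UNet, 400 epochs, GPU,
external dermoscopy data) is out of scope. The harness trains a ~4-level
numpy encoder–decoder (two 2× pooling levels, skip connections, sigmoid
head, default width 4, ~3k parameters) with Adam (lr 1e-3, step decay ×0.95
every 5 epochs), full analytic gradients — the loss layer supplies
dL/dP and the network backpropagates it, so no autodiff framework is
needed. Deterministic given the seed.

Two protocol choices matter:

* **Prior warmup.** The shape term is enabled only after the first two
  thirds of the epochs (`prior_warmup_epochs`, configurable). The prior is
  a regularizer of an already-roughly-segmenting model: from random
  initialization, its smoothing branch makes the trivial uniform prediction
  a strong attractor (uniform maps zero the shape term), and training
  collapses. This mirrors the large-scale protocol, where the prior only
  ever acts on a pretrained backbone.
* **Capacity.** Width 4 keeps the baseline (no-prior) model weak enough
  that it reproduces internal-hole errors on held-out data — the failure
  mode the prior exists to fix. A wider toy net simply memorizes
  "bright-inside-dark is still lesion" from the training labels and the
  ablation loses its subject.

The ablation runner trains all four variants (`none`, `unsegmented`,
`non_scaled`, `segmented`) on identical data and seeds and reports
test-split mIoU/mAP/Dice/Jaccard plus residual internal-hole pixels. The
acceptance experiment uses 40 samples (24 train / 8 val / 8 test), 64×64
images with 3 confuser holes each, 30 epochs, seeds {0, 1, 2}; the
acceptance property is that the segmented prior leaves fewer internal-hole
pixels than the baseline in at least 2 of 3 seeds, with a guard that the
prior model's Dice stays above 80% (a collapsed model trivially has no
false negatives and must not count). Problem sizes were chosen so the whole
suite runs in minutes on one CPU.

`preprocess` follows the usual pipeline: aspect-preserving resize so the
longer side hits `target_side` (default 256), symmetric padding to square,
nearest-neighbor for masks; random flips (image and mask jointly) and
brightness shifts (image only) exist as training-time augmentation with
mild defaults, since the reference pipeline states the operations but not
their magnitudes.

## Known limitations

* `PsN` at a border false-negative pixel whose ray immediately exits gives
  the tie value 0, i.e. internal hole; irrelevant for lesions that do not
  touch the frame (the simulator guarantees a margin) but a caveat for
  full-frame masks.
* The loss treats branch structure as locally constant; its "gradient" is a
  subgradient of a piecewise-smooth function and finite-difference checks
  must stay away from guard thresholds.
* The shape term is O(pixels × mean segment length) per evaluation; the
  label-dependent pair/ray tables are cached per label (keyed by mask
  bytes, FIFO-bounded), which makes repeated evaluation cheap during
  training but means very large grids (≫ 256²) need chunking that this
  package does not implement.
* Dataset-level mAP averages per-sample APs; class-absent samples drop that
  class's AP with a warning rather than imputing a score.
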