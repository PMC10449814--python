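# Methods

## Problem and scope

The package implements, at desk scale, the full analysis chain used to map
savanna tree species in very-high-resolution UAV RGB orthomosaics by
semantic segmentation: reference-data preparation (tiling, spatially
separated splits, on-the-fly augmentation), class-imbalance-aware CNN
training with smoothed-curve model selection, offset-tiled ensemble
inference with majority voting, accuracy assessment (per-class P/R/F1,
overall accuracy, Cohen's κ, mIoU), and per-class landscape metrics with
F1-vs-metric regressions.  Because no field imagery is distributed, a
seeded synthetic-scene generator stands in for the orthomosaics; it is
first-class, tested code, and every downstream stage runs on its output.

## Synthetic scenes

A scene is an (H, W, 3) 8-bit raster plus an integer class mask and a class
table, with a ground sampling distance of 1.2 cm per pixel by default.  The
generator emulates the statistical structure of delineated savanna
reference data rather than its photographic appearance:

- **Imbalanced composition.** Each class has a target pixel share; the
  `savanna` composition uses 17 classes — a dominant bare-ground/herb
  background (55%) and 16 woody classes whose shares decay geometrically.
- **Patchy canopies.** Non-background classes are placed as elliptical
  patches (gamma-distributed areas around `patch_area_mean`, eccentricity
  set by `elongation`) by rejection sampling until the class pixel budget
  is met.  A pixel keeps the first label painted on it, and the final patch
  of each class is truncated at the budget, so empirical shares track
  targets to within a patch boundary.
- **Fine-grained texture.** Class appearance is a base colour plus
  band-passed Gaussian noise at a class-specific granule scale — leaf-scale
  texture is the discriminative signal, not crown outline.

What the generator does **not** model: photogrammetric artefacts and data
gaps, shadows and view-dependent illumination, within-class morphological
gradients, and between-class texture correlation.  Passing tests therefore
demonstrate that the pipeline's computations are correct and that the
training loop can exploit colour/texture differences; they do not
demonstrate field-data accuracy.

The phenology perturbation shifts each class's pixels along a seeded
class-specific colour direction (towards mid-grey, 50–90 intensity units at
full strength) plus seeded noise (σ = 10 at full strength), linearly in a
strength knob in [0, 1]; the mask is untouched and strength 0 is the
identity.  The drift magnitude was set so that a fully drifted scene
degrades a trained model's accuracy by an amount comparable to a seasonal
re-survey, giving the transfer ladder a clear signal; it is a stand-in, not
a calibrated model of phenology.  At intermediate strengths the degradation
is usually, but not on every seed, monotone for weakly trained models.

## Training

- **Class weights.** w_i = p_i^(−x) with p_i the class's share of training
  pixels; x = 0 gives uniform weights.  Per-architecture defaults 0.1
  (U-Net), 0.005 (FC-DenseNet), 0.2 (DeepLabv3+).  Absent classes get
  weight 0 and are excluded from the loss.
- **Loss.** Weighted categorical cross-entropy: mean over pixels of
  w_c · (−log p̂_c) for the true class c, probabilities clipped at 1e-7
  before the log (numerical safety only, far below metric tolerances).
- **Optimiser.** Adam with α = 1e-4, β₁ = 0.9, β₂ = 0.999 as library
  defaults; at most 300 epochs with early stopping after 40 epochs without
  validation-mIoU improvement; parameters snapshotted every epoch.
- **Batch size.** Auto rule batch(T) = batch(1024) · (1024/T)², reference
  batch 4 at 1024 px; explicit override allowed.
- **Model selection.** The validation-mIoU curve is smoothed by a
  tricube-weighted local *quadratic* regression (LOESS, span 0.3 of the
  logged epochs — the span is a package choice) and the epoch at the
  smoothed maximum is selected, ties towards the earliest epoch.
  Validation mIoU is computed on whole validation scenes with the base
  tile grid only (zero offset); test-time inference uses the full 16-layer
  vote.  Logs shorter than 3 epochs skip smoothing and use the raw argmax.

### The numpy network core

The three architectures run on a small reverse-mode autodiff engine inside
the package (`savseg.nn`): stride-1 'same' convolution with optional
dilation, 2×2 max pooling, nearest-neighbour upsampling, channel
concatenation, ReLU, global average pooling with spatial broadcast, and a
fused weighted softmax cross-entropy; parameters use He-normal init and
float64 arithmetic.  Every operator is finite-difference checked in the
test suite (max observed gradient error ~1e-10).  Architectures are built
at configurable scale:

- **U-Net**: symmetric encoder/decoder, two 3×3 conv+ReLU per stage,
  skip concatenations, 1×1 classifier head.
- **FC-DenseNet**: dense blocks (each layer consumes the concatenation of
  all previous outputs) on both paths, transition convolutions around
  pooling/upsampling.
- **DeepLabv3+**: small encoder, atrous spatial pyramid pooling with one
  branch per configured dilation rate plus an image-pooling branch,
  decoder fusing a 1/2-resolution low-level feature map.

The full-size variants used on GPU clusters are configuration presets
(`models.PRESETS`), not test targets.  Network inputs are zero-centred
((x/255) − 0.5); without centring, weighted-loss training of small nets
can sit on a constant-background plateau for tens of epochs.

## Inference

Predictions are written to 16 co-registered layers: tile grids offset by
{0, 25, 50, 75}% of the tile size in each axis (4 × 4 offsets, zero offset
included).  For each offset the scene is mirror-padded so the grid covers
every pixel; each pixel thus receives exactly 16 votes, and the final label
is the per-pixel modal class, ties broken towards the lowest class id.
Voting acts on hard labels; probability averaging is available off-default.

## Evaluation and landscape metrics

The confusion matrix is stored rows = truth, columns = prediction.
P_i = cm_ii/colsum_i, R_i = cm_ii/rowsum_i, F1 = 2PR/(P+R) with 0/0
defined as 0 and flagged; OA = trace/total; κ = (OA − p_e)/(1 − p_e) with
p_e from the row/column marginals; mIoU excludes classes absent from both
masks.  Mean F1 averages all classes by default; a flag excludes the
background.  Paired t-tests across model configurations use the exact
t-distribution p-value, error on zero-variance differences, and apply no
multiple-testing correction (the number of tests is the caller's record).

Patches are maximal connected components (8-connectivity default, matching
the landscapemetrics convention; 4 available).  The smallest circumscribing
circle is computed on pixel corner points via the randomised incremental
(Welzl-type) algorithm on the convex hull, so a single pixel has radius
√2/2; compactness is CIRCLE = 1 − a_patch/a_circle (0 = circular, → 1 =
elongated).  Both the raw circle area and the ratio are reported; the
regressions use the ratio by default.  Class F1 is regressed on each metric
by OLS with df = n − 2 (14 for 16 vegetation classes, background excluded).
Absent classes are reported as absent (NaN), never zero.

## Desk-scale experiment

The shipped preset trains a depth-2, base-width-8 U-Net on three 256×256
three-class scenes (tile 64, batch 2, 30 epochs, Adam lr 1e-2 — a higher
rate than the full-scale default, appropriate for a net of ~10⁴ parameters)
with a 128×128 validation and a 128×128 test scene, all spatially disjoint
by construction.  On this preset the full chain reaches held-out mean F1
≥ 0.8 and mIoU ≥ 0.7 within the 30-epoch budget, and the perturbation
ladder (strengths 0, 0.5, 1) shows monotone F1 degradation.  These sizes
were chosen so the complete experiment runs in a few minutes on one CPU;
they are the package's stated study conditions for all end-to-end checks.

## Numerical choices and degenerate inputs

- Single-label masks: later classes never overwrite earlier ones.
- Tiling discards partial edge tiles (training); inference pads instead.
- Augmentation applies geometry to image and mask jointly (bilinear /
  nearest), photometry to the image only; each operation is skipped when
  its drawn factor is the identity, so degenerate ranges are bit-exact
  no-ops.  Brightness is multiplicative, contrast scales deviation from
  the image mean, saturation scales HSV-S; order flip → rotate → scale →
  brightness → contrast → saturation.
- Scenes smaller than one tile yield an empty tile list plus a warning.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; sub-seeds are derived with a CRC-based
  stable hash, so runs are reproducible across processes.

## Known limitations

- Float64 CPU training limits practical model scale; the full-size presets
  exist for completeness, not for routine use here.
- The synthetic textures are statistically stationary within a class;
  real canopies are not, so real-data F1 will be lower at equal effort.
- The perturbation model changes appearance only; real seasonal change also
  alters crown geometry, which this stand-in cannot represent.
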