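# Methods

## Problem and pipeline

The package segments pigmented skin lesions in RGB dermoscopic images as a
binary pixel-labelling task (lesion = positive).  The pipeline has three
stages — preprocessing, model training, postprocessing — each independently
usable as a library module and as a CLI subcommand.

## Synthetic fixtures

`fixtures` renders dermoscopy-like scenes so the whole pipeline is testable
without clinical data.  A scene is composed of:

* a warm skin-tone background (base RGB ≈ (205, 155, 135) with a per-image
  tint jitter of ±12), low-frequency mottle (Gaussian-filtered noise,
  σ = image/16, amplitude 8 intensity levels) and short-range grain
  (σ = 0.8-blurred white noise rescaled to sd 3);
* a lesion: an ellipse (aspect 0.6–1.0, random orientation) whose radius is
  perturbed by 3–6 random Fourier harmonics (relative amplitude
  0.02–0.10/√k) to mimic irregular borders.  The binary ground-truth mask
  is thresholded at the exact pixel count that realizes a target area
  fraction drawn from `lesion_area_fraction_range` (default 0.05–0.30 of
  the frame), so the realized area is always inside the requested interval.
  The *image* boundary is then softened with a Gaussian (σ = 2 px),
  mirroring the relation between a crisp annotated mask and a photographic
  lesion edge; lesion color sits `lesion_contrast` (default 60) levels
  below the skin, weighted toward the blue/green channels to look brown;
* hairs: 0–6 quadratic Bézier strokes spanning the frame with a gentle bow,
  thickness 2 px, intensity 40, composited over the image through a
  0.5-px-blurred alpha.  Hairs never touch the mask, and their exact
  footprint is retained on the sample for diagnostics.  The hair RNG
  stream is independent of the lesion/noise stream, so the same seed with
  `hair_count_range=(0,0)` reproduces the identical hairless scene — this
  is what the hair-removal efficacy tests difference against.

Grain is spatially correlated (σ 0.8) and small (sd 3) on purpose: in real
captures sensor noise is smoothed by demosaicing and compression, and dark
hairs are far darker than the noise envelope.  This keeps the black
top-hat response of hairless skin below the default detection threshold,
which is the regime the morphological hair remover is designed for.

What the fixtures do **not** model: rulers, color-calibration patches,
vignettes and black frames, multi-focal or border-touching lesions, and
real photometric variability across acquisition devices.  A model that
recovers these synthetic lesions has demonstrated that the implementation
learns and generalizes at desk scale — not that it reaches clinical
accuracy on real dermoscopy.

## Hair removal

Grayscale conversion uses BT.601 luma weights (0.299, 0.587, 0.114).  The
black top-hat is `closing(X) − X` with a 9×9 rectangular structuring
element by default (wide enough to close 1–3 px hairs at 256×256;
`disk` and `cross` shapes are selectable), computed with reflect border
handling to avoid spurious frame response.  The response is thresholded at
10 of 255 — deliberately low, since false positives only hand benign
pixels to the inpainter — then dilated by 1 px to cover the soft halo of a
hair stroke.  Inpainting default is `nearest`: each masked pixel takes its
nearest unmasked neighbor's value (Euclidean distance transform) and the
filled region is blended with a Gaussian of σ = `inpaint_radius`/2
(default radius 3).  A biharmonic fill is available as `biharmonic`.
Processing order in the pipeline is resize first, then hair removal, so
the structuring element and threshold are calibrated at one scale.

## Architectures

All convolutions are 3×3 except the 1×1 heads, gates and shortcut
projections; every conv is followed by ReLU (with batch normalization
inside blocks), and each network ends in a 1×1 convolution with a sigmoid
producing a per-pixel lesion probability at input resolution.  Convolution
padding replicates the border pixel, so a spatially constant input yields
a spatially constant output (no positional leakage from a zero border).
The convolution-layer census — the auditable contract of each builder —
counts every convolution-type layer exactly once:

| arch | composition | convs |
|---|---|---|
| UNet | 4 encoder + bridge + 4 decoder double-conv blocks (8+2+8), two channel-halving up-convs in the deepest decoders, 1×1 head | 21 |
| ResUNet | 7 sublevels × 2-conv pre-activation residual units, 1×1 head | 15 |
| ResUNet++ | stem (2 conv + 1×1 shortcut), 3 SE residual encoders (×3), ASPP bridge (4 dilated + 1×1 fuse), 3 attention gates (×3) + 3 residual decoders (×3), output ASPP (5), 1×1 head | 41 |

Design choices where the architecture family leaves freedom:

* **Upsampling.**  Default is nearest-neighbor; in the UNet the two deepest
  decoders pair the upsample with a dedicated 3×3 channel-halving
  convolution (the classic "up-convolution" read as upsample + conv).  A
  2×2 stride-2 transposed convolution is selectable
  (`upsample_mode="transposed_conv"`), but it is not the default because
  each output parity then sees a different kernel tap, which breaks the
  flat-response property above and invites checkerboard artifacts.
* **ResUNet shortcuts** are parameter-free (channel zero-padding or
  truncation) so the 15-conv census stays clean; ResUNet++ units use 1×1
  projections, which its census includes.
* **Attention gates** are additive: `skip · σ(ψ(ReLU(W_g·g + W_x·skip)))`
  with W_g, W_x, ψ all 1×1 convolutions (three per gate).
* **SE blocks** squeeze with global average pooling and two dense layers
  (ratio 8); dense layers are not convolutions and are excluded from the
  census.
* **ASPP** uses dilation rates {1, 6, 12, 18} with a 1×1 fusion.
* Channel width: `base_width` 16 doubling per depth (desk scale); 64 is
  the full-scale setting.  The census is width-invariant.

## Losses

Let X be the mask and Y the predicted probability map; sums run over
pixels, per sample, then average over the batch; pixel losses (BCE, focal)
average over everything.  The smoothing constant is 1 throughout the
overlap family.

* BCE: mean of −(X log Y + (1−X) log(1−Y)), Y clamped to [1e−7, 1−1e−7].
* Dice: default `canonical_2x`, 1 − (2ΣXY+s)/(ΣX+ΣY+s), so a perfect
  prediction scores exactly 0 and 1−loss matches DC = 2TP/(2TP+FP+FN) on
  hard masks.  The exponent-free `as_printed` variant
  1 − (ΣXY+s)/(ΣX+ΣY+s), which appears in print, is retained for
  comparison; it leaves a residual s-dependent loss at X = Y.
* BCE–Dice: 0.2·BCE + 0.8·Dice; the combiner is exposed directly on
  precomputed component values.
* Focal: default follows the multiplicative form −γ(1−p)·log p with
  γ = 0.75 (the stated range of the modulating factor is 0–1); the
  canonical exponentiated form −(1−p)^γ·log p is selectable.
* Tversky: 1 − (s+ΣXY)/(s+ΣXY+βΣ(1−X)Y+(1−β)ΣX(1−Y)), β = 1/2.  At
  β = 1/2 the Tversky index **is** the Dice ratio: TL with smoothing s
  equals the canonical 2× dice loss with smoothing 2s (not the
  exponent-free printed dice — the denominators differ).  The test suite
  asserts the correct identity.
* Focal Tversky: as printed, carries no focal exponent and coincides with
  the Tversky loss; an optional (1−TI)^(1/γ) exponent mode is off by
  default rather than silently "correcting" the formula.

## Training schedule

ADAM (β₁ 0.9, β₂ 0.999, ε 1e−8) with SGDR: within cycle k of length T_k,
lr(t) = lr_min + (lr_max·0.9^k − lr_min)/2 · (1 + cos(π t / T_k)),
lr_max = 1e−2, lr_min = 1e−4, T₀ = 5, T_{k+1} = round-half-up(1.5 T_k),
cumulative cap 300 epochs with the last cycle clipped
(5, 8, 12, 18, 27, 41, 62, 93, 34).  The 10% per-cycle reduction applies
to the restart peak only, so the floor stays at 1e−4 and every restart
peak is strictly below the previous one.  The learning rate is
piecewise-constant within an epoch.  Early stopping watches the validation
loss with patience 20; the retained checkpoint is the best-validation-JAC
epoch, JAC being the headline metric.  Augmentation (default preset
`combo7`: the three spatial transforms plus HSV shift, RGB shift,
brightness, contrast, each with probability 0.5) is applied on the fly
per batch rather than materializing an enlarged dataset — equivalent in
expectation with a smaller footprint.

## Postprocessing

TTA averages `T⁻¹(model(T(image)))` in probability space over
{identity, horizontal flip, vertical flip, rotate180}, adding
rotate90/270 automatically for square inputs; pixel-level transforms are
excluded because their inverses are undefined in mask space.  The CRF is a
fully connected two-label model: unary −log(clip(p, 1e−8)), Potts
compatibility, a Gaussian spatial kernel (weight 3, σ 3 px) and a
bilateral appearance kernel (weight 5, σ_space 50 px, σ_color 13) relaxed
by 5 mean-field iterations.  Bilateral message passing uses a
bilateral-grid approximation: splat onto a grid sampled at one cell per σ
in (y, x, r, g, b), blur with a unit Gaussian, slice back with linear
interpolation, and normalize by a homogeneous weight channel.  The
pipeline order is TTA first, then CRF on the averaged map.  The CRF
parameters are fixed, not learned: no objective for fitting them is
defined in this setting, so the refinement is inference-only.

## Evaluation

Metrics are computed per image and then averaged.  Degenerate conventions:
both masks empty → all metrics 1; an undefined ratio (empty prediction or
empty truth with a nonempty counterpart) → 0.  The Jaccard report bins
per-image JAC at width 0.05 and reports the fraction exceeding 0.786, the
inter-observer agreement bar used as the clinical-relevance threshold.
ROC/AUC pools pixels across images and integrates by the trapezoid rule.

## Numerical engine

`lesionseg.nn` is a compact reverse-mode autodiff engine on float32 NumPy
arrays: conv2d via im2col matmul (input gradients via the flipped-kernel
correlation, verified against an explicit scatter oracle), 2×2 max
pooling, nearest-neighbor upsampling, 2×2 stride-2 transposed conv,
batch-norm composed from primitives with running statistics for inference,
and ADAM.  The backward pass releases each graph node's closure and
gradient as soon as its parents are updated, keeping peak memory flat
across training steps.  Training is bit-reproducible on one device for a
fixed seed (seeded init, data order and augmentation stream).

## Problem sizes

The test suite exercises desk-scale configurations chosen to keep the
whole suite in the minutes range on one CPU: 32–128 px images, widths
4–8, and an end-to-end recovery run of 64 training images at 64×64 for 30
epochs (three seeds, majority vote, held-out mean JAC ≥ 0.80 — typical
runs reach ≈ 0.94).  Full-scale settings (256×256, width 64, 300-epoch
SGDR budget) are the configured defaults but are not exercised in CI.

## Known limitations

* The synthetic task is much easier than real dermoscopy; passing the
  recovery criterion shows implementation correctness, not clinical
  performance.
* The bilateral grid is an approximation of exact dense-CRF message
  passing; with default σ it is accurate to the granularity of one grid
  cell.
* The engine is single-device, float32, CPU-only; no mixed precision or
  distributed training.
* Only binary lesion/background heads are provided.
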