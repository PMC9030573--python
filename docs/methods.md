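# Methods

This note records the model, the numerical and design choices, and what
the synthetic benchmark does and does not demonstrate.

## Pipeline model

A whole-slide image is processed as a tile-based data structure: the
grid has ceil(H/U) × ceil(W/U) cells of U×U pixels (0-based, half-open
pixel windows [iU, iU+U) × [jU, jU+U); edge tiles are reflection-padded
to full size for the network and cropped back when stitching, with the
padded strip of their label masks set to the ignore value so it never
carries gradient or metric weight). Tissue detection happens once per
slide: the thumbnail (block-mean downsample, default 1/32; 1/16 in the
desk-scale experiments) is converted to Rec. 601 luminance and split by
Otsu's threshold — the vectorized cumulative-moment form of the
between-class-variance maximizer, ties broken toward the lowest level,
with pixels at or below the threshold (darker than glass) taken as
tissue. A tile is flagged for processing when its tissue fraction
reaches `min_tissue_fraction` (default 0.05). Only flagged tiles pass
through the network; everything else is background by fiat, which is
the entire speed mechanism — no other shortcut is taken.

The segmentation rule is `tumor ⇔ p_tumor ≥ α` with α = 0.5. The
boundary is deliberately inclusive: thresholding at exact equality
would select a measure-zero set, and the inclusive convention is the
one asserted by tests.

## Network

The modified FCN is a five-block VGG16-style encoder (13 convolutions
of 3×3/stride 1/pad 1, ReLU after each; 2×2/stride-2 floor-mode max
pooling after each block) with the two fc-derived layers of the
original FCN removed, a zero-padding layer before block 1 (pad 100 at
the 512-px default, giving the 512 → 712 transformation), a 1×1 score
convolution to the class channels, a single 64×64/stride-32 transposed
convolution initialized to bilinear interpolation, a center crop back
to the input size, and a per-pixel softmax. Floor-mode pooling yields
the 22×22 pool5 trace (712 → 356 → 178 → 89 → 44 → 22); the transposed
convolution maps n → (n−1)·32 + 64, so 22 → 736, and the centered crop
offset is (736−512)/2 = 112. The crop offset is always derived from the
size formula, never hard-coded, so smaller input/pad combinations (128
px with pad 32 in the tests) satisfy the same output-size contract.

Two dropout layers (ratio 0.5) regularize the pool5 features
immediately before the score convolution. An earlier variant placed one
dropout after the score convolution; on a 2-channel score map that
randomly zeroes entire class logits (with ×2 inverted-dropout scaling)
and measurably prevents convergence even on a trivially color-separable
task, so both dropouts sit on the deep features — the role they played
on the fc layers of the original architecture, whose positions the
shallow network no longer has.

Inputs are standardized inside the model as (x − 128)/64 per channel.
Encoder convolutions are He-initialized, the score convolution starts
at zero (an untrained model therefore emits exactly uniform class
probabilities), and the upsampler starts as bilinear interpolation.
Transfer learning is implemented as a loading contract: any checkpoint
tensor whose name and shape match is copied; mismatches are reported
(non-strict) or rejected (strict). Checkpoints are `.npz` files with a
JSON sidecar recording the spec and tensor shapes.

The layer stack (convolution via k² shifted channel-mixing BLAS
products, pooling with cached argmax, transposed convolution, inverted
dropout, softmax–cross-entropy with an ignore label, SGD with momentum
and L2 weight decay) is written directly in numpy with explicit
backward passes; every backward pass is verified against centered
finite differences with float32-aware step sizes.

## Training scheme

Tile weights: le¹ = 1 iff the annotated-tumor fraction of the tile,
ϑ = |tumor px| / U², reaches γ = 0.05, else 0. After round h the
error fraction e = |{prediction ≠ reference, reference ≠ ignore}| / U²
is measured for **every** tissue tile (predictions thresholded at α),
and leʰ⁺¹ = leʰ + χ when e ≥ γ (χ = 1 by default; the increment's value
is not dictated by the scheme, and a unit increment keeps weights
interpretable as sampling multiplicities). Updating all tiles — not
just those currently sampled — lets a background tile that produces
false positives re-enter the training set, which is how the scheme
"increases the learning effort" on false positives. Weights never
decrease; this monotonicity is asserted per round.

A tile of weight w contributes round(w) independently augmented copies
per round: a uniformly chosen right-angle rotation (0/90/180/270°),
optional ±5° jitter rotation (off by default — the printed rotation
recipe is internally inconsistent, and right angles are the part that
is unambiguous), horizontal/vertical mirror flips with probability 0.5
each, and photometric jitter of contrast ±20%, saturation ±20%,
brightness ±12.5%, sampled uniformly. Geometric transforms apply
identically to tile and mask; photometric jitter to the tile only.
Empirical jitter draws are tested to stay within and to cover ≥ 90% of
each stated range.

Because Eq-style initialization gives pure-background tiles weight 0,
the model would otherwise never see healthy tissue; a configurable
negative-sampling quota (`negative_quota` admitted background tiles per
positively weighted tile, default 0) re-admits a random subset each
round. The synthetic experiments use 0.5.

Focus sampling converts background-labeled tissue pixels to the ignore
label when they lie in regions flagged as partially annotated (or
within an optional dilation band of annotations). The loss is softmax
cross-entropy; pixels labeled 255 contribute exactly zero value and
zero gradient — asserted bit-exactly, not approximately. The loss can
be summed over pixels (the convention under which a learning rate of
1×10⁻¹⁰ with weight decay 5×10⁻⁴ and dropout 0.5 is meaningful, and the
package default) or averaged over valid pixels with a correspondingly
larger rate for small-tile experiments. SGD momentum is 0.9; the
optimizer's velocity persists across boosting rounds.

## Synthetic slides

The generator emulates exactly the structure the pipeline assumes and
nothing more: a near-white glass background (level 242 ± noise), an
elongated smooth tissue blob with an H&E-like pink-purple palette and
low-frequency texture (bimodal grayscale histogram, so Otsu separation
is guaranteed by construction and then verified, not assumed), and
elliptical foci in the three TNM classes with major-axis physical
length sampled within (2, 4] mm (macro; the TNM class is open-ended
and is capped so foci fit desk-scale slides), (0.2, 2] mm (micro) and
(0.02, 0.2] mm (ITC; the lower bound keeps foci at least a few pixels),
eccentricity (minor/major) in [0.4, 1]. Foci must lie entirely in
tissue and may not overlap; large classes are proposed constructively
along the tissue's long axis (a > 2 mm ellipse fits a 2048-px slide
only near the diagonal), smaller ones by rejection sampling whose size
draw decays toward the class lower bound as rejections accumulate —
all draws remain within the class bounds. Partial labeling erases
round(fraction · n) whole connected components from the training mask
(regions, not pixel speckle, mirroring how real annotation gaps look).
Everything derives from one integer seed via `SeedSequence`, and equal
seeds reproduce byte-identical rasters.

What passing the synthetic benchmark shows: the pipeline's plumbing is
lossless, its numeric rules match independent oracles, and the training
scheme can recover color/texture-separable foci — including at ITC
scale — from partially labeled data. What it does not show: performance
on real H&E stains, where tumor-vs-stroma contrast is textural and
nuclear rather than chromatic, stain variability is large, and
annotation noise is not component-shaped. The generator makes no
attempt at nucleus-level realism.

## Desk-scale experiment

`metaseg.experiments.synthetic_recovery` runs the full pipeline at a
size a single CPU finishes in minutes: 10 slides of 2048×2048 px at
1 µm/px (8 training — 6 malignant with 1 macro + 2 micro + 3 ITC foci
and 20% of label components erased, 2 benign — and 2 malignant held
out), 128-px tiles, a width-reduced network (channels 8/16/32/32/32,
pad 32; topology unchanged), two boosting rounds of two epochs each,
mean-reduced loss with learning rate 0.01, batch 4, at most 60
tumor-bearing tiles kept per slide. Held-out tumor IoU is computed from
confusion counts summed over the test slides; macro-focus recall counts
a planted macro focus as found when any predicted tumor pixel falls
inside its ellipse. Typical seeds reach tumor IoU ≈ 0.97–0.98 with
macro recall 1.0 in ≈ 4 minutes.

## Numerical conventions and degenerate inputs

* Otsu on a single-level or empty histogram raises a degenerate-input
  error rather than returning an arbitrary level.
* Metrics: a class absent from prediction and truth scores 1.0 on all
  its metrics; any other vanishing denominator scores 0.0. Ignore
  pixels are excluded from every count. Per-slide mIoU is the mean of
  the background and tumor IoUs (the per-class reading of the metric);
  cohort values average per-slide values, and both views are reported.
* Cohort confidence intervals use Student's t on per-slide values
  (mean, SD with ddof = 1, SE, 95% CI); with fewer than two slides the
  CI is reported as NaN with a warning.
* Confusion counts are integers and additive over partitions, which is
  what makes tile-wise and slide-level evaluation provably equivalent.
* All tensors are float32; computation is single-threaded BLAS, so
  seeded runs are bit-reproducible on one CPU.

## Known limitations

* No pyramidal/tiled-TIFF streaming: slides are held in memory, which
  bounds practical slide size to what fits in RAM; the tile data
  structure itself has no such bound.
* The numpy network trains desk-scale models; at the full 512-px,
  VGG16-width configuration it is functional but not fast enough for
  cohort-scale training on one CPU.
* No stain normalization, no post-processing of the stitched mask
  (hole filling / small-component removal), and no overlapping tiles —
  the stitched mask can show tile-boundary seams for borderline
  probabilities.
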