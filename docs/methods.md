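# Methods

## Problem and model

Retinal vessel segmentation is per-pixel binary classification of thin,
bifurcating, curvilinear structures whose width spans more than an
order of magnitude and whose contrast against the background is low and
spatially varying. The architecture addresses exactly those properties:
residual blocks ease optimisation of a deeper feature extractor;
the inception bottleneck (parallel 1×1/3×3/5×5 kernels) widens the
receptive-field diversity where the representation is coarsest; and
full-scale skip connections let every decoder stage consult both
fine-grained edge information (shallow encoder maps, max-pooled down)
and semantic context (deeper decoder maps, bilinearly upsampled), so
capillaries are not lost during upsampling.

Fusion topology: the decoder stage at level `t` of a depth-`L` model
always fuses exactly `L` sources — encoder levels `1..t` resized by
max pooling (factors `2^(t−s)`) and the deeper chain `t+1..L`
(decoder stages, with the bottleneck standing at level `L`) resized by
bilinear upsampling (factors `2^(s−t)`). Max pooling is used on the
way down (preserves thin bright activations), bilinear interpolation on
the way up (transposed convolutions are avoided for their checkerboard
artifacts). Each source is adapted by a 3×3 conv → batch-norm → ReLU to
a uniform `fusion_channels` width before concatenation, and a residual
block maps the concatenation to the stage's output width. There is a
single output head; no deep supervision.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `depth` | 4 | encoder levels; inputs must divide `2^depth`, matching the `/16` requirement of 565×584 or 304×304 frames (handled by reflect padding) |
| `base_channels` | 32 | width at full resolution, doubling per level — the standard U-Net rule |
| `fusion_channels` | 32 | per-source width inside each full-scale fusion, uniform across sources |
| `bottleneck_channels` | deepest encoder width | output of the inception projection |
| loss | BCE | consistent with per-pixel classification; `bce_plus_dice` available for stronger class-imbalance pressure |
| optimiser / lr | Adam, 1e-3 | standard for U-Net variants at these scales |
| `threshold` | 0.5 | probability binarisation cutoff; ≥ convention at the boundary |
| preprocessing | bilateral d=9, σ_color=0.1, σ_space=5; CLAHE clip 2.0, 8×8 tiles; γ=1.2 | common fundus-enhancement settings; all overridable, and the whole chain can be disabled per dataset (contrast enhancement helps fundus-style images and tends to blur OCT-A capillaries into the background) |
| augmentation | rotation ±30°, shift ±10%, both flips | modest, topology-preserving transforms; expanded sets are materialised on disk so a dataset size is a reproducible artifact, and the stated totals include the originals |

Grayscale conversion defaults to BT.601 luminance; the green channel is
offered because it carries the best vessel contrast in fundus
photography. Metrics are restricted to the field-of-view ROI whenever a
sample carries one (pixels outside the aperture are uninformative);
this is switchable since conventions differ between published
evaluations. Aggregation defaults to micro (pooled counts), with macro
(per-image averaging) available — the two differ whenever image sizes
or difficulty differ, which is one reason published precision/recall/F1
triples are not always jointly consistent with the F1 formula.

## Numerical substrate

No GPU framework is used. `vesselseg.nn` is a ~400-line reverse-mode
autodiff over float32 numpy arrays: convolution is im2col + GEMM;
bilinear resizing is a pair of dense separable interpolation matrices
(half-pixel-centre convention, edge-clamped), whose transpose is the
exact backward pass; max-pool ties split the gradient evenly
(deterministic); batch-norm keeps float64 running statistics with the
unbiased-variance correction for inference. BCE is computed from logits
with the log-sum-exp-stable form; sigmoid outputs are clamped to
[1e-6, 1 − 1e-6] so probability maps remain strictly inside (0, 1) in
float32. Gradient correctness is enforced by central-difference checks
through the full wiring (residual add, concat, pooling, upsampling,
batch-norm) in the test suite. Determinism: given seeds, the only
randomness is initialisation and batch order; repeated runs on
single-threaded CPU are bit-identical.

Degenerate cases follow explicit conventions: metrics with a zero
denominator return 0 and are flagged `undefined` rather than raising;
constant images are fixed points of the bilateral filter and map to
constants under CLAHE; a rotation by a multiple of 90° snaps its
transform matrix so that e.g. 180° is an exact index reversal (an
involution on masks), immune to `sin(π) ≈ 1e−16` float noise.

## Synthetic data: what it does and does not emulate

The generator grows `n_trees` vessel trees from the image border as
recursively bifurcating polyline strokes: each branch shortens and
narrows (`width_decay` per level), children deviate by approximately
`branch_angle_deg`, and segments carry gentle curvature jitter. Strokes
are rasterised with a 1-pixel anti-aliased edge; the binary mask is the
soft coverage thresholded at 0.5, which keeps mask and image
geometrically aligned. The image is a smooth low-frequency illumination
field (peak-to-trough `illumination_gradient`) darkened multiplicatively
by `vessel_contrast` under the vessels, plus Gaussian sensor noise,
clipped to [0, 1]. Per-node RNG keying makes the sample a pure function
of (seed, index) and makes deeper `branch_depth` strictly extend — not
reshuffle — shallower trees, so expected vessel count is monotone in
depth by construction.

This reproduces the statistical features the architecture targets —
dark, bifurcating, width-decaying curvilinear structures on an uneven
background — but not optic disc, fovea, lesions, central vessel reflex,
or OCT-A speckle. Passing tests therefore demonstrate that the
implementation is correct and that the model can learn vessel-like
topology from realistic contrast and noise; they do not certify
clinical-grade performance on real fundus photographs.

Reference statistics (frozen in the tests from a 100-sample Monte-Carlo
run of the 128×128 / 2-tree / depth-4 configuration): vessel-pixel
fraction 0.0350 ± 0.0142 (mean ± sd); samples are asserted within
mean ± 4 sd.

## Problem sizes

The bundled experiments are sized for a single CPU: the demo pipeline
uses 16 synthetic 64×64 training images augmented to 32, a
depth-3 / 8-channel model and 200 optimiser steps (~1 minute); the
capacity check trains the same model for 300 steps on 8 images and
reaches training-set micro-F1 ≥ 0.95, with the training loss falling
more than tenfold. Scaling the same code to benchmark protocols
(thousands of augmented whole images, 100 epochs × 100 steps) is a
configuration change, not a code change, but is far outside desk-scale
runtimes and outside the bundled test surface.

## Known limitations

* Whole-image training only; no patch sampling, validation split, early
  stopping or learning-rate schedules.
* The numpy substrate is single-process and unbatched beyond the batch
  dimension; it is deliberately simple rather than fast.
* The bilateral filter window is all pixels within the configured
  diameter (scikit-image backend); very large diameters are slow.
* `augment_to_count` cycles sources in order, so replicate counts per
  source differ by at most one — exact balance only when the expansion
  factor is integral.
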