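# Methods

This note records the model, the numerical conventions, the synthetic-data
design, and the genuinely open design choices made in `slidestream`, in the
package's own words.

## Streaming model

The engine trains a CNN of *local* layers (convolution, max-pooling,
evaluation-mode batch normalization, ReLU) followed by a global-max-pool +
dense binary head, on one weakly labelled image per optimization step.

**Coordinates and padding.** All coordinates are 0-based `(row, col)`; all
rectangles are half-open. Images are virtually padded right/bottom with
white to the next multiple of the stack's total stride `S`, so every core
tile's output interval is integral at the final feature scale. Inside
convolutions, zero padding applies at the *global* image boundary only;
tile borders in the interior see true neighbor pixels via the halo. White
`(255,255,255)` is the out-of-raster fill in image space; it is *not* the
convolution padding value — the two regimes are tracked separately, which
is what makes tiled and dense computation bit-comparable (observed
agreement is at float64 rounding level, ~1e−15 relative).

**Halo arithmetic.** For a layer `(k, s, p)`, the input interval feeding
output `[a, b)` is `[a·s − p, (b−1)·s + k − p)`. Composing this map from
the head down to the image and measuring the overhang beyond one core
stride gives the halo margin `M`. Each tile materializes exactly its
backward-mapped window per layer; clipped-off overhang at the global
boundary is re-created as that layer's own zero padding (max-pool pads with
−∞ so padding never wins).

**Frozen batch normalization.** Streaming is incompatible with batch
statistics computed over the full image, so BN runs in evaluation mode:
`y = γ(x − μ)/sqrt(σ² + ε) + β` with fixed `(μ, σ²)` (ε default `1e−5`) and
gradients flowing to `γ, β` only.

**Backward pass.** The head makes the feature-map gradient one-hot per
channel. Only tiles containing at least one argmax are re-forwarded
(activations kept for that tile only) and back-propagated; a counter
reports how many. Head gradients are closed-form: `∂L/∂w = g·maxima`,
`∂L/∂b = g`. Argmax ties resolve to the smallest `(row, col)` in row-major
order *across the whole image*, independent of tile visit order, by
comparing candidate positions lexicographically during the running-max
merge.

**Skipping.** A tile is skipped when its fetched (possibly augmented) input
window is entirely within `whiteness_delta` (default 0, "pure white") of
white. Skipping is pure exclusion; to make silent bias impossible, the
engine evaluates each *distinct skipped-window signature* (window shape +
boundary-padding amounts — identical all-white windows have identical
outputs, and there are only a handful of signatures per image) on an
all-white input and flags any channel whose maximum a skipped tile would
have attained or tied (`ForwardRecord.white_win_channels`). On such inputs
results may differ from the unskipped run; the flag says so.

**Scheduling.** The pipelined mode overlaps fetching/augmenting the next
tile (producer thread, bounded queue) with computing the current one.
Results are bit-identical to sequential execution because per-tile work is
independent and merge order is preserved.

**Memory contract.** The engine holds at most one tile's window pyramid
plus the running maxima. Instrumentation records the peak single-buffer
spatial area; it is bounded by `(tile + 2M)²` and measured constant from
512² to 8192² canvases.

## Augmentation

One `AugmentationPlan` is drawn per image (flips Bernoulli(0.5); rotation
uniform in [−180°, 180°); per-stain rotation angles uniform in [−10°, 10°];
per-stain concentration factors uniform in [0.5, 1.5]), so patches are
mutually consistent by construction.

*Geometric*: flips then rotation about the canvas center, bilinear
interpolation, white fill. A patch is produced by inverse-mapping its
rectangle, fetching the source bounding box plus a 2-pixel margin, and
resampling — cost proportional to the patch. *Color*: RGB → optical
density `OD = −log10((v + 1)/256)` (the `+1` guard keeps OD finite;
`OD(255) = 0` exactly), closed-form two-variable non-negative least squares
against the stain matrix, concentration scaling, recomposition through the
perturbed matrix, rounding back to 8 bits. Pure white is a fixed point.
Stain vectors are rotated within span(H, E) — the rotation plane is not
otherwise determined in 3-D OD space — then clipped at zero and
re-normalized; the clip can shrink the effective angle when a rotation
drives a component negative. The default stain matrix is the
Ruifrok-Johnston H&E pair, unit-normalized, user-overridable. The affine
transform is applied before the pixel-local stain transform. No scaling
augmentation is included.

## Label noise

`estimate_transition` counts annotator labels against ground truth,
pooling counts when several annotators are given (pooling, rather than
averaging per-annotator matrices, weights annotators by how many labels
they contributed); an empty truth class falls back to add-one smoothing.
The loss is `−ln (Tᵀ(1−p, p))[y]`, with the analytic gradient used by the
training step. `T = I` reduces to binary cross-entropy.

## LN post-processing

Pipeline order: one binary dilation with the 3×3 diamond (cross) kernel →
removal of 4-connected components with strictly fewer than 4096 pixels
(the 4096 threshold is meant for detector-scale masks at 7.36 µm/pixel;
`min_area` is configurable) → outer border following (Moore neighbor
tracing, 8-connected, terminating on a repeated pixel/entry-direction
state) of each surviving component in top-left scan order. Holes are not
reported; the attached area is the filled pixel count. One dilation
iteration and 8-connectivity for components are package choices where the
procedure leaves them open; the dilation kernel itself fixes
4-connectivity for the dilation step.

## Evaluation statistics

Confusion metrics use the standard definitions; zero-denominator metrics
return an explicit `None` marker rather than 0, except MCC → 0 (common
convention). Clopper–Pearson bounds come from beta quantiles. AUC is the
midrank Mann–Whitney statistic (ties credited 0.5). DeLong variance uses
the structural components `V10`/`V01`; the paired test aligns tables by
instance id and is two-sided; a zero variance difference with zero AUC
difference reports `p = 1`. Slide scores are node-score maxima, so
"aggregate then threshold" equals "threshold then any". Classification is
inclusive (`score ≥ threshold` is positive); the default operating
threshold is 0.4 with a 0.15 screening alternative, and
`pick_threshold_mcc` selects a grid threshold by maximal MCC (ties to the
smallest). `count_cv` divides the n−1 standard deviation by the mean, with
0 for constant (including all-zero) counts.

## Synthetic studies

The generator emulates the structure the method depends on, not histology:
a white canvas (background exactly `(255,255,255)`, so the skip rule and
white-fill conventions are exercised), disjoint elliptical nodes filled
with clumpy hematoxylin-dominant texture (smoothed thresholded noise over a
weak eosin stroma), and, in positive nodes, one eosin-rich focus whose
physical diameter is drawn from the clinical size class: macrometastasis
2–4 mm, micrometastasis 0.2–2 mm, isolated tumor cells 0.06–0.2 mm. The
default scale is 7.36 µm/pixel (the detector's 1.25× magnification) so all
classes fit on 512–2048 px canvases; at 0.46 µm/pixel (20×) the same
classes map to the full-scale pixel ranges (micrometastasis 435–4348 px).
A focus that cannot fit its node is resampled, failing after 100 attempts.
Rendering composes the 2-channel concentration field through the stain
matrix and `od_to_rgb`, so the stain-augmentation math runs end to end on
generated data. A single `difficulty` scalar (default 1.0) controls the
eosin concentration gap between focus and background.

What the generator does **not** emulate: nuclei-scale morphology, scanner
noise and compression artifacts, stain variability between laboratories,
tissue folds, or non-node tissue. Passing tests therefore demonstrate the
*mechanics* (streaming equivalence, augmentation consistency, weak-label
learnability of a color-separable lesion, pipeline plumbing) — not
clinical-grade metastasis detection.

Manifests are plain files (PNG images and masks, CSV labels, YAML
parameters with per-file SHA-256 checksums); regeneration from the
recorded seed is byte-identical, and checksum mismatches abort a run
naming the file.

## Demo classifier

`demo_net` (stride 8: conv s2 → maxpool 2 → conv → maxpool 2 → conv, 8/16/16
channels) is trained from scratch, which with a global-max head is
delicate: gradients reach the convolutions only through one argmax pixel
per channel, and purely random color projections sometimes never make the
lesion the argmax. Three initialization choices make training reliable for
any seed: (1) a leading frozen-BN fixed to `x → 1 − x`, so white background
maps to zero and tissue absorbance drives the maxima; (2) the first
convolution's first two channels start as stain-deconvolution color priors
— the hematoxylin OD direction and the eosin direction orthogonalized
against it (amplified 2×, so small eosin foci compete with dense
hematoxylin texture); (3) deeper convolutions use identity-preserving
(Dirac) initialization plus noise, so the color channels survive the stack
until the head learns which ones predict the label. With these choices the
demo net reaches held-out AUC ≥ 0.95 within one epoch on the default
synthetic study across every initialization seed tried; AdamW
(lr `1e−3`, betas (0.9, 0.999), decoupled weight decay 0.01) is the default
optimizer for the demo, with the learning rate configurable.

## Problem sizes

The shipped tests and the acceptance script use: 20 random nets on
128–512 px images for streamed-vs-dense equivalence; 50 random plans for
augmentation equivalence; a 200-slide training / 60-slide held-out study of
512² single-node images (tile 256) for learnability, early-stopped at
held-out AUC 0.90 within the 10-epoch bound; canvases from 512² to 8192²
(tile 64) for the memory contract. These sizes were chosen as the smallest
at which each property is meaningfully exercised.

## Known limitations

* Only the listed local layer family is streamable; attention or other
  global operators are rejected by construction.
* The dense full-image reference (`naive_reference`) is the test oracle and
  is only feasible at desk scale.
* Pyramidal-TIFF reading selects no level automatically; callers pass the
  raster they want classified.
* DeLong's Wald CI degenerates at AUC 1.0 (zero variance) — exact
  small-sample CIs are out of scope.
* The white-patch deviation flag is conservative on ties (it flags
  equality even when row-major order would have kept the content patch's
  argmax).
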