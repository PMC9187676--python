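# slidestream

Memory-bounded, end-to-end training and inference of convolutional
classifiers on gigapixel stained-tissue images, with the surrounding
clinical-workflow machinery: lymph-node (LN) instance post-processing from
segmentation masks, weak-label noise correction, and diagnostic-accuracy
statistics.

## The problem

Digitized pathology slides are routinely billions of pixels. Training a CNN
on a whole slide with only a slide- or node-level label ("metastasis present
/ absent") is attractive — no pixel annotation needed — but a naive
backpropagation pass would materialize feature maps far beyond any
accelerator's memory. `slidestream` implements a *streaming* scheme:

* **Tiled forward pass with halo margins.** The image domain is split into
  disjoint core tiles. Each tile is fetched together with a halo margin
  `M` computed by backward interval arithmetic over the layer stack (for
  output interval `[a, b)` through a layer with kernel `k`, stride `s`,
  padding `p`, the input interval is `[a·s − p, (b−1)·s + k − p)`), so tiled
  computation is *exactly* equal to dense full-image computation.
* **Global-max head.** The final feature map is reduced per channel by its
  spatial maximum and scored by a dense layer, `logit = wᵀ·max F + b`. Tiny
  lesions survive the reduction, and the feature-map gradient is nonzero
  only at one argmax location per channel.
* **Gradient checkpointing with contribution skipping.** Feature maps are
  discarded after each tile; the backward pass re-forwards *only* tiles that
  contain a channel argmax. Tiles whose input window is pure white
  (background padding) are skipped outright. Peak retained activation area
  is bounded by `(tile + 2M)²` regardless of image size.
* **Patch-consistent augmentation.** All random draws — flips, rotation
  (−180°…180°), stain-matrix rotation (−10°…10°), stain concentration
  factors (0.5×…1.5×) — are sampled once per image; any output patch can
  then be produced independently by inverse-mapping it to a source window
  (affine) or pixel-locally in optical-density stain space
  (`OD = −log10((v+1)/256)`, decomposed through an H&E stain matrix).
* **Label-noise forward correction.** Training minimizes
  `−ln (Tᵀ(1−p, p))[y]` where `T` is a row-stochastic label-noise transition
  matrix estimated from annotator labels against ground truth.
* **LN post-processing and statistics.** Binary detector masks become node
  instances (3×3 diamond dilation → removal of areas under 4096 px → outer
  border following); instances are scored, thresholded (0.4 operating /
  0.15 screening), and counted per slide and study; evaluation covers
  sensitivity/specificity/PPV/NPV/MCC, exact (Clopper–Pearson) binomial
  CIs, ROC AUC with DeLong variance and the paired DeLong test, and the
  coefficient of variation of repeated counts.

Real cohorts of this kind are private, so the package ships a synthetic
generator: white-padded canvases with elliptical nodes of
hematoxylin-dominant texture and optional planted eosin-rich foci whose
physical diameters follow the clinical size classes (macrometastasis
≥ 2 mm, micrometastasis 0.2–2 mm, isolated tumor cells < 0.2 mm at a stated
µm/pixel), rendered through the same stain optical-density model the
augmentation uses.

## Worked example

```bash
python examples/05_diagnostic_statistics.py
```

```
confusion counts: TP=263 FP=12 FN=32 TN=849 (n=1156)
sensitivity 0.8915  (95% exact CI 0.8503-0.9246)
specificity 0.9861
MCC         0.8986
```

Of 295 truly positive LN images the classifier recalls 89.15% (the exact
binomial CI spans 85.03–92.46%); of 861 negatives it clears 98.61%; the
Matthews correlation coefficient 0.8986 summarizes the whole confusion
table in one balanced number.

The other examples each demonstrate one capability and print what they
compute:

```bash
python examples/01_streamed_vs_naive.py      # tiled == dense, to float precision
python examples/02_patch_augmentation.py     # patch == whole-image augmentation
python examples/03_train_on_synthetic_slides.py  # weak labels -> held-out AUC 1.00
python examples/04_assess_slides.py          # masks -> node counts vs planted truth
```

A thin CLI mirrors the library for shell use:
`slidestream simulate|train|predict|heatmap|evaluate|assess --help`.

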