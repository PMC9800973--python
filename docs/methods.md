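# Methods

## Model

`pestyolo` implements the AgriPest-YOLO detector: a YOLOv5s-family
single-stage network adapted to light-trap pest imagery. The assumptions
inherited from that lineage are: objects are representable by axis-aligned
boxes predicted as offsets from nine anchor priors (three per stride 8, 16,
32); each grid cell is responsible for objects whose center falls in it
(extended to the two nearest neighbour cells at train time); confidence is
the product of an objectness term — trained toward Pr(object)·IoU — and a
per-class sigmoid probability.

### Architecture choices left open by the design and how they were fixed

* **Attention reduction ratio r** — default **32**, the convention of the
  coordinate-attention family the block derives from; configurable
  (`ModelConfig.cla_reduction`). Small-width models need a smaller r so the
  bottleneck C/r stays ≥ 1 and divides C; the test models use r = 4.
* **Leaky ReLU slope** in CLA — default **0.1**, configurable.
* **Batch normalization in CLA** — applied to the shared bottleneck only
  (the block diagram places a BN there even though the equation omits it);
  the directional expansion convs have none.
* **The local-context factor is unbounded** (it is not passed through a
  sigmoid), so CLA can amplify as well as attenuate; a bounded variant is
  available behind `cla_bounded_local` (off by default).
* **CLA insertion point** — after the CSP block's fusing convolution,
  acting on the block output, in all four backbone CSP stages.
* **GSPPF channel bookkeeping** (not printed anywhere): entry conv
  C_in→C_in, four groups of C_in/4, each internal SPPF C_in/4→C_in/4 with a
  half-width hidden layer (C_in/8), exit conv C_in→C_out. This keeps GSPPF a
  drop-in replacement for SPPF. Consequence worth knowing: with this
  bookkeeping GSPPF has slightly *fewer* parameters than the SPPF it
  replaces (≈650k vs ≈657k at C=512), so the published +0.27 M parameter
  delta of the full model is reproduced only partially (+0.05 M, from CLA);
  both profile figures remain within the ±5% band the open choices imply.
* **Group-2 input**: the cascade starts fresh at group 2
  (y₂ = SPPF(v₂), no cumulative add) — the grouped equations are
  implemented literally.
* **Decode** — the standard v5-style decode: center (2σ(t)−0.5+cell)·stride,
  size (2σ(t))²·anchor; at inference score = σ(obj)·max_c σ(cls_c).

### Profiling

`count_parameters` enumerates learnable scalars exactly (conv weights and
biases, BN affine pairs; running statistics are buffers, not parameters).
`count_flops` reports 2×MACs (+ bias adds) of one forward pass: the network
is traced at a small reference input, each convolution's pixel count is
measured again at the doubled input to obtain its scaling exponent (spatial
maps scale quadratically with input size; CLA's pooled-profile convs scale
linearly), and the totals are extrapolated exactly to the requested size.
BN, activations and pooling comparisons are excluded, matching the
convention under which the reference figures were produced. A test
cross-checks traced shapes against real forward output shapes.

## Training

SGD with momentum 0.937 and weight decay 5e-4, initial learning rate 0.01
with cosine decay to 10% (`lr_final_frac`), batch size configurable
(default 16). The total loss

    L = (0.05·L_box + 1.0·L_obj + 0.5·L_cls) · 64

is scaled by a **nominal batch of 64** — the gradient-accumulation target of
the recipe this package follows — rather than the actual batch size;
without that factor, small-batch desk-scale runs take effective steps ~30×
smaller than the published recipe and converge far too slowly. Objectness
BCE is weighted 4.0/1.0/0.4 across strides 8/16/32 (small objects dominate
the fine grid). The objectness target at an assigned cell is the decoded
box's clipped GIoU with its ground truth, detached from the graph.
Assignment matches a label to every anchor within a 4× w/h ratio, in its
cell plus the two nearest neighbour cells. Head biases are initialised so
objectness starts rare (log(8/S²)) and classes near-uniform, which
stabilises the first epochs.

Initialisation is random (He-normal, seeded); no pretrained weights are
used anywhere. Images are letterboxed to the square input size with
gray-114 padding. Boxes surviving geometric augmentation with less than 10%
of their original area are dropped (`min_area_frac`).

## Synthetic scenes

The generator (`pestyolo.synthetic`) emulates the statistics that make
light-trap data hard, not their photographic appearance: a bright textured
background with a mild illumination gradient; dark elliptical insects with
per-class aspect/shade/leg signatures (classification is learnable but not
trivial); unlabeled mid-gray clutter blobs and unlabeled white reflection
discs to exercise false-positive suppression; a long-tailed class prior
(geometric decay) unless explicit proportions are given; log-uniform
relative scales, default (0.005, 0.05) with rare large outliers (2%
probability, up to 0.4) mirroring the heavy concentration of tiny insects
with occasional very large ones; and a `density` knob that places insects
adjacent to existing ones to create overlapping labeled pairs. Labels are
the exact bounding boxes of rendered pixels. Everything derives from one
seed; the same seed reproduces byte-identical label files.

What passing tests on these scenes does **not** show: robustness to real
photographic nuisances (blur, JPEG artefacts, species-level appearance
variation, 3-D pose), detection of insects at the extreme small end on real
sensors, or transfer of trained weights to real data. The scenes validate
the *mechanics* — assignment, losses, decoding, suppression, evaluation —
not field accuracy.

## Test-gate problem sizes

The end-to-end gates run a width-0.25 model at 128×128 with 2 classes and
attention reduction 4: the overfit gate trains on 8 scenes of 4 fairly
large insects (relative scale 0.12–0.28) for 150 epochs, batch 2,
augmentations off, anchors fitted to the fixture labels by the 1−IoU
k-means, and must reach train mAP@0.5 ≥ 0.9; the short-training gate runs
5 epochs over 50 scenes with the full augmentation pipeline and requires
the mean total loss to decrease from first to last epoch. Batch 2 rather
than 1 matters: with single-image batches the BatchNorm running statistics
calibrate poorly and evaluation-mode accuracy lags training-mode fits.

## Noise-robustness harness

`robustness_sweep` evaluates a checkpoint under salt-&-pepper noise at
fractions 0.005–0.05 in steps of 0.005 (plus the clean baseline; a Gaussian
mode with mean 0.1, σ 0.05 on the [0,1] scale is also provided). Level 0
bypasses the noise path entirely, so its row must equal plain evaluation
bit for bit. The degradation *trend* is asserted statistically rather than
step-by-step: on an 8-image fixture the between-level sampling jitter of
mAP@0.5 reaches ±0.05, and an overfit model detects large fixture insects
through ≤5% flipped pixels almost unimpeded at IoU 0.5 — pixel noise erodes
localization precision first. The gate therefore checks, on
mAP@[0.5:0.95]: no noise level exceeds the clean baseline by more than
0.02; the heaviest level is strictly below baseline; and the rank
correlation between level and mAP is negative.

## Numerical choices

* All network arithmetic is float32; oracles and metric code run in
  float64. Sigmoid inputs are clipped at ±60 (saturation is exact there in
  float32).
* BatchNorm uses eps 1e-3 and momentum 0.03 (lineage convention); training
  mode normalises with batch statistics and maintains running moments for
  evaluation.
* GIoU denominators carry a 1e-9 guard; degenerate zero-area boxes in IoU
  are defined as zero overlap and logged.
* Max-pool gradient routes to the first maximum in each window (ties broken
  by flattened argmax), making forward and backward bitwise deterministic.
* Soft-NMS keeps boxes whose rescored confidence stays above a final
  threshold (default 1e-3, needed for a finite output); suppression in both
  NMS variants is per class.
* AP uses the exact all-point interpolated integral; a 101-point grid is
  available for cross-checks. Classes absent from the ground truth are
  excluded from mAP means and logged, not scored zero.
* k-means anchor fitting uses the 1−IoU(w,h) distance, 50 Lloyd iterations,
  seeded initialisation, centroids sorted by area and split 3/3/3 across
  strides; fewer than 9 labels falls back to the preset anchors.

## Known limitations

* CPU-only and NumPy-bound: a full-size 640×640 forward pass takes ~15 s on
  one core; training at the published scale (300 epochs, batch 16, 640²,
  25k images) is out of reach here — the package demonstrates correctness
  at reduced problem sizes, not field-scale accuracy.
* The published mAP figures on the 24-class field dataset are not
  reproducible from this repository (they require the external dataset and
  GPU-scale training) and are out of scope.
* Mixed precision, EMA weights, warm-up scheduling, distributed training
  and model export are not implemented.
* The parameter profile of the full model reproduces the published count
  only to ~3% (see the GSPPF bookkeeping note above).
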