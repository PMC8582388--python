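# Methods

## Problem setting

A whole-slide image (WSI) carries one binary label — carcinoma present or
absent — and, for a subset of positive slides, loose polygon annotations
that cover the lesions plus some adjacent stroma. No pixel-level ground
truth is available at training time. The pipeline learns a tile-level
classifier from these weak labels and aggregates tile probabilities to a
slide score by taking their maximum: a slide is as suspicious as its most
suspicious tile. This max rule is what makes weak supervision workable —
a positive slide needs only one confidently positive tile, and on
negative slides every tile is a guaranteed negative.

## Tissue detection and tiling

Tissue is separated from the near-white background by Otsu's method on a
grayscale thumbnail. Conventions, all configurable:

- Grayscale uses fixed luminance weights 0.299/0.587/0.114, so masks are
  reproducible across color variations of the same scan.
- Otsu runs on a 1/32 thumbnail by default (`otsu_downsample`); the
  threshold maximizes between-class variance over all 256 cut points and
  is computed from cumulative moments. When several cuts tie (a plateau,
  e.g. two delta masses), the plateau midpoint is returned so the
  threshold sits between the modes rather than at the first tie. A
  histogram concentrated in one bin is flagged degenerate and produces an
  empty mask: an all-background slide has no tissue, not all tissue.
- Tiles are enumerated row-major on a grid with stride = tile_size/2 at
  the working magnification; coordinates are 0-based level-0 pixels,
  half-open footprints. A tile is kept iff its tissue fraction is at
  least `min_tissue_fraction` (default 0.1). Boundary tiles extending
  past the slide are dropped, not padded, avoiding synthetic border
  artifacts at the cost of a sub-tile margin of uncovered tissue.
- Working magnifications are integer divisors of the scan magnification;
  a ×10 tile from a ×20 scan is a block-mean 2× downsample of a
  double-size level-0 region. Block-mean resampling is deterministic and
  alias-free enough for texture statistics.

## Balanced sampling and hard mining

Phase 1 draws slides from a queue that alternates (positive, negative)
pairs. Each epoch, the minority class list is repeated
⌈majority/minority⌉ times, truncated to the majority count, and both
lists are shuffled with a per-epoch seed — this simultaneously guarantees
strict alternation and that every slide appears at least once per epoch.
Each batch holds batch_size/2 tiles from each slide of one pair, so every
phase-1 batch is exactly label-balanced. On annotated positives the
candidate set is restricted to tiles whose *center* lies inside an
annotation polygon (even-odd rule); loose annotations already include a
stromal margin, so center containment is an adequate and deterministic
membership test. Sampling is without replacement when enough candidates
exist, with replacement otherwise; an annotated slide whose polygons
contain no tile center raises an error naming the slide rather than
being silently skipped — it indicates broken annotations.

Phase 2 alternates frozen-model inference and training. For each slide
visited in queue order, the model scores all candidate tiles and the k
highest-probability tiles are selected (ties broken row-major, making
mining deterministic for a fixed model); each selected tile inherits the
slide label. On negative slides this selects precisely the model's
current false positives. Selected tiles accumulate until the subset
reaches N, then one training pass of N/batch_size batches runs on the
shuffled subset and the overflow carries to the next subset, so total
tiles trained equals N × passes. Mining restricts annotated positives to
their annotated regions, consistent with phase 1; each training pass
iterates its N tiles once.

Open-choice defaults: the phase switch happens after
`random_phase_epochs` = 1 (the head must move off its zero
initialization before top-k selection is meaningful), and model updates
occur between triggers so mining always uses the freshest weights.

## Model and partial fine-tuning

Transfer learning updates only the batch-normalization affine parameters
(scale γ, shift β per channel) and the final classification layer; all
convolutional weights stay frozen. The classification head is a single
sigmoid unit on the globally pooled feature vector — with EfficientNetB1
(1280 pooled features, BN channel total 31,024) that leaves
2·31,024 + 1,281 = 63,329 trainable scalars. The EfficientNet variants
are represented by exact per-tensor architecture bookkeeping (compound
scaling with width/depth coefficients, divisor-8 filter rounding, MBConv
expand/depthwise/squeeze-excite/project structure), which fixes the
freezing and counting semantics; their convolutional forward pass is out
of scope here.

The runnable backbone is `tiny-test-cnn`: two stride-2 3×3 convolutions
(channels 8 and 16, He-initialized from a fixed seed and permanently
frozen) each followed by batch norm and ReLU, global average pooling, and
a sigmoid head — 65 trainable scalars under partial fine-tuning. Forward
and backward passes are written in numpy; the backward path only needs
gradients for BN affine and head parameters, but still propagates through
the second convolution, both ReLUs and both batch norms. Gradients for
the full trunk are deliberately not implemented, so `train_step` requires
partial fine-tuning to have been applied. Adam is implemented alongside
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). BN running statistics update in
training mode with momentum 0.9 (a flag can freeze them); only γ and β
receive gradients, and the running buffers never count as trainable.
Tiles are scaled to [0, 1] and standardized with fixed mean 0.5 / scale
0.25.

## Training schedule

Adam at learning rate 0.001 with step decay rate = 0.001 × 0.95^⌊epoch/2⌋
(0-based epochs, so decay takes effect at epochs 2, 4, …), binary cross
entropy, batch size 32, k = 4, N = 256. Validation loss is *slide-level*
binary cross entropy on the max-tile probability — the same decision rule
used at test time — with probabilities clipped to [1e-7, 1−1e-7] before
the logarithm (the clip floor slightly affects printed log-loss values
and is therefore fixed and documented). Early stopping fires after 10
epochs without strict validation-loss improvement; equal losses keep the
earlier epoch, NaN losses never count as improvement, and the returned
model is the lowest-validation-loss checkpoint. A `max_epochs` bound
(default 100) caps runaway runs.

## Inference and evaluation

Slide inference enumerates tissue tiles at stride tile_size/2 and scores
them in batches; the batch size cannot change outputs. A slide with zero
tissue tiles scores 0 and is flagged `no-tissue` instead of raising, so
manifest-level evaluation never aborts — a slide without tissue cannot be
called positive. Heatmaps composite overlapping tiles by pixel-wise
maximum, matching the slide-level max semantics; the raw grid is also
serialized as CSV for exact round-tripping.

ROC AUC is computed from average ranks, equal to
(#concordant + 0.5·#tied)/(n_pos·n_neg); the test suite checks it against
both an O(n²) pair-enumeration oracle and scikit-learn. Confidence
intervals are percentile bootstrap (2.5th/97.5th percentiles) over slides
resampled with replacement, 1000 iterations by default; single-class AUC
resamples are redrawn and counted, and data degenerate enough that more
than half of resamples are single-class raise an error. Threshold calls
use p ≥ threshold (ties to positive). The subtype table stratifies false
positives and true negatives among negative slides by benign subtype,
with within-block percentages to one decimal; untagged negatives bucket
as `unspecified`.

## Synthetic slides

The generator emulates the structural assumptions the pipeline relies
on, not histology itself: a near-white background (gray ≈ 245);
irregular tissue blobs (thresholded correlated noise around random
centers, mean gray ≈ 185) carrying smooth low-contrast texture
(σ ≈ 6 after heavy smoothing); and, on positive slides, lesion regions
occupying `lesion_fraction` (default 0.25) of the tissue with darker,
higher-contrast, higher-frequency texture (mean ≈ 150, σ ≈ 35, light
smoothing). The lesion mask is the top quantile of a smooth random field
inside tissue, which yields a near-exact area fraction in a few
connected components. Loose annotations are per-component convex hulls
buffered by `annotation_dilation` = 12 px, clipped to bounds — they
cover ≥ 95% of lesion pixels plus surrounding stroma, mimicking coarse
pathologist outlines. Half of positive slides are annotated by default
(the cohort the pipeline emulates annotated 96 of 191 positives);
negatives draw benign subtypes from configurable weights, fibroadenoma-
dominant by default. All draws are keyed on (spec.seed, label, slide
seed), giving byte-identical images per call.

What this does **not** emulate: H&E color and stain variation, nuclear
morphology, pen marks and scanner artifacts, pyramid file formats, and
the scale of real WSIs (gigapixels vs 10⁵ pixels here). Passing tests
therefore demonstrate that the mechanics — tiling, queueing, mining,
aggregation, evaluation — behave as specified and that the pipeline can
recover a planted, texture-separable signal from weak labels; they say
nothing about accuracy on real histopathology.

## Problem sizes

The end-to-end check trains the tiny backbone on a 40-slide synthetic
dataset (12+12 train, 4+4 validation, 4+4 held-out test; 320 px slides,
tile 64 at ×20, k = 4, N = 256, batch 32, 20 epochs), chosen so the full
suite completes in well under a minute per stage on one CPU while still
exercising both phases, mining triggers, early-stopping bookkeeping and
held-out evaluation. On this data a converged model reaches held-out
slide AUC ≥ 0.95 and its selected top-k tiles on positive slides overlap
the planted lesions — the weak-label localization that hard mining
exists to produce.

## Known limitations

- The EfficientNet entries count and freeze parameters exactly but do
  not run; plugging in a real pre-trained trunk requires implementing
  the `ModelContract` around a deep-learning runtime.
- The tiny backbone's 65 trainable parameters learn texture-statistic
  separations, not morphology; its absolute probabilities move slowly
  from 0.5, so threshold-0.5 confusion tables on miniature runs are
  conservative even when ranking is perfect.
- Bootstrap CIs resample slides, not patients; correlated slides from
  one patient would narrow intervals optimistically.
- Annotation membership is tile-center containment; tiles straddling a
  polygon boundary are classified by their center alone.
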