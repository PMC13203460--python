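# Methods

## The problem

Live weight and carcass composition (carcass weight, fat mass, lean mass)
are the quantities a sheep producer most needs and least likes to measure:
weighing requires handling, and CT-derived composition is slow and costly.
`ovimorph` implements a non-invasive alternative: paired dorsal/lateral RGB
images of a ewe plus two cheap tabular covariates (body condition score,
size category) feed a multimodal deep regression that predicts all four
traits at once.  Because real flock data of this kind is not freely
redistributable, the package also ships a calibrated synthetic-flock
generator so every stage of the pipeline is testable end to end at desk
scale.

## Synthetic flock model

Phenotypes.  Live weight LW follows a normal distribution truncated to
[48.0, 88.5] kg with mean 62.4 kg and SD 8.7 kg.  Because truncating a
normal shrinks its SD, sampling N(62.4, 8.7²) and rejecting out-of-range
draws would produce an SD below the target; the generator instead solves
the two truncated-moment equations for the latent parameters (μ₀ ≈ 59.35,
σ₀ ≈ 11.28 for the defaults) so the *observed* flock reproduces the target
moments.  This is the generator's truncation correction.

Fat mass FM is lognormal, ln FM ~ N(ln 5.5, 0.55²), truncated to
[0.88, 17.64] kg, with its Gaussian latent correlated (ρ = 0.6) with the
live-weight latent: heavier ewes are on average fatter.  The live-weight
latent is rejection-sampled against its own bounds first — keeping its
marginal exactly the truncated normal above — and the fat-mass latent is
then drawn conditionally.  Rejection (never clipping) avoids probability
atoms at the bounds.

Carcass weight is a dressing fraction (0.44) of live weight plus N(0, 0.5²)
noise; bone mass is a fixed fraction (0.18) of carcass weight; lean mass is
the remainder, so fat + lean + bone = carcass holds to machine precision by
construction.  Fat mass is capped at 0.55 × carcass weight, which bounds
lean mass away from zero (lean ≥ 0.27 × carcass).  The dressing, bone and
cap fractions are generator inventions chosen once for biological
plausibility of a mature ewe; all are overridable through
`FlockCalibration`.

Tabular covariates are *derived*, not drawn: BCS is the within-flock
rank-quantile of the fat ratio FM/CW mapped to the conventional 1–5 scale
in 0.5 steps (ties broken by animal id for determinism), and the size
category comes from live-weight tertiles.  The half-point 1–5 BCS scale is
the common field convention; it is an assumption of the generator, not a
property of any particular real flock.

Rendering.  Each view is a schematic silhouette: a two-lobed body
(thoracic and rump lobes) whose half-width is

    w = intercept + b·LW + c·mod(size)·FM        [pixels]

with per-view coefficients, plus a pure-red reference bar standing in for
the 40 cm marker, and additive Gaussian background and fleece-texture
noise.  Two choices matter:

* **Decodability.**  With zero noise, ordinary least squares of live
  weight on dorsal body-pixel area reaches R² ≥ 0.95 over 200 animals —
  the targets must be learnable from the images or model tests would test
  nothing.
* **Multimodality by construction.**  The fat-mass slope `c` is modulated
  by the size category (0.5 / 1.0 / 1.5).  Fat mass therefore cannot be
  read off the image alone; the tabular record carries the missing
  context.  This is what gives the image-only ablation its expected
  deficit.

One pseudo-random stream is derived per (seed, animal id, view), so flocks
are order-independent and bit-reproducible.

What the renders do **not** emulate: photorealism, wool texture, breed
differences, perspective or lens distortion, occlusion, lighting
direction.  Tests passing on this generator demonstrate that the
architectures, losses and harnesses behave as specified on data with a
known recoverable structure — not that the models reach any particular
accuracy on real animals.

## Dataset assembly and leakage control

Splitting always happens at the animal level: both views and every
augmented copy of one ewe land in exactly one partition or fold.  Counts
follow floor(train ratio · n) / ceil(val ratio · n) / remainder — with 156
animals at 70/15/15 that is 109/24/23 — and k-fold assignment is a seeded
shuffle followed by round-robin (fold sizes differ by at most one).

Augmentation is training-set only and comes in two framings: a
deterministic 5-variant materialization per image (original, horizontal
flip, ±8° rotation, +20% brightness) used when a dataset is written to
disk, and an on-the-fly stochastic mode (flip p = 0.5, rotation uniform in
±8°, brightness factor uniform in 1 ± 0.2) for per-epoch variation.
Rotation fills exposed corners with the median border colour; brightness
is multiplicative with clipping to [0, 1].  `verify_no_leakage` audits an
assembled dataset for animals spanning partitions and augmented images
outside the training set; the pipeline refuses to train on data that fails
the audit.

## Architectures

All three families share one contract: inputs (dorsal image, lateral
image, 4-dim tabular encoding), outputs 4 unconstrained regressands.
Images are channel-normalized with the standard ImageNet statistics.

* **baseline_concat** — per-view stride-2 conv backbone (shared weights by
  default), global average pooling, channel concatenation with an MLP
  encoding of the tabular record, fully connected head.  ReLU.
* **attention_fusion** — the backbone gains a CBAM block after every conv
  stage (channel gate: shared two-layer bottleneck over average- and
  max-pooled descriptors; spatial gate: 7×7 convolution over channel-mean
  and channel-max maps, replicate-padded so the gate stays
  translation-symmetric at borders).  The final feature map's spatial
  positions act as visual tokens; the tabular MLP output is the single
  query of a scaled dot-product cross-attention over them, and the
  attended summary is concatenated with the tabular vector.  Swish.
* **token_fusion** — both views are cut into non-overlapping patches,
  linearly projected, given learned positional and per-view role
  embeddings, and joined into one sequence with a dedicated tabular token
  prepended at position 0 (its own positional embedding).  A pre-norm
  transformer encoder processes the joint sequence; the tabular token's
  terminal state feeds a linear head.  GELU.

Design points that were genuinely open: CBAM placement (after each stage),
view merging for the transformer (one joint sequence with additive
view-role embeddings — the simplest mechanism that lets self-attention see
both views and the covariates at every layer), and whether the two views
share backbone weights (shared by default, configurable).  The published
backbone capacities (ResNet18 / EfficientNet-B3 / ViT-Base at 224 px) are
exposed as named width presets, but the defaults are deliberately tiny —
the families and fusion mechanisms, not the capacity, are what the package
specifies and tests.  Loading pretrained weights is possible through the
checkpoint mechanism but never required.

The numerical core is a small reverse-mode autodiff over float64 numpy
arrays (`ovimorph.nn`) with exactly the operations these models need;
gradients of every layer are tested against central differences.

## Training

The multi-task objective is the homoscedastic task-uncertainty loss
L = Σ_t exp(−s_t)·MSE_t + s_t with learnable log-variances s_t initialized
to −0.5 for all four targets (equal initial weighting).  Targets are
z-scored per task from the training set before the loss sees them (and
un-scaled at prediction), so the log-variances start on comparable scales.
At the per-task optimum s_t = ln MSE_t; with all s_t = 0 the loss is the
plain MSE sum.  Validation loss for early stopping uses the same form with
the current log-variances frozen.

Optimizers: Adam, AdamW (decoupled decay), SGD with momentum.  Schedules:
step decay (base·γ^⌊e/step⌋), cosine (base·(1+cos πe/T)/2), and linear
warmup from zero into cosine; all clamp at their final value beyond the
horizon.  When no horizon is given the cosine span defaults to the
configured epoch budget.  Early stopping restores the lowest-validation-
loss checkpoint and stops `patience` epochs after it (15 by default).  A
divergence guard abandons a run whose batch MSE stops being finite and
keeps the best checkpoint to date — this is what lets grid search rank a
diverging learning rate last instead of crashing.

Per-epoch train MAE in the history is the running mean over the epoch's
(pre-update) batch predictions; validation MAE is a full pass.  With a
fixed seed and the single-threaded loop, two fits produce bit-identical
histories.  The five-run stability protocol derives five distinct
initialization seeds from one base seed via `SeedSequence` and reports the
across-run SD of validation MAE.

The harnesses — exhaustive grid search (winner: lowest validation MAE
averaged over targets, first-seen tie-break), animal-level k-fold CV, and
the single-change ablation suite (backbone swap, single-task, image-only,
concatenation fusion, no augmentation/regularization) — all operate on the
estimator interface through `sklearn.base.clone`, so every variant trains
under identical seeds and splits.

## Evaluation

MAE, RMSE, coefficient-of-determination R² (1 − SSE/SST; squared Pearson
is also reported but is not the headline number, since an uncalibrated
predictor can correlate perfectly while agreeing poorly), and MAPE in
percent.  Agreement statistics: Lin's CCC with population (1/n) moments —
the standard definition — and Bland–Altman with the *sample* SD of paired
differences, limits at bias ± 1.96 SD, plus the slope of difference
against pair mean as a proportional-bias diagnostic.  Model comparisons
use paired t-tests and the Wilcoxon signed-rank test on absolute errors
(zeros dropped, average ranks, exact null up to n = 25 after zero removal,
normal approximation with continuity correction beyond), two-sided
throughout: a direction is claimed only when the data shows it.

## Explainability

Grad-CAM for regression: channel weights are the spatial mean of
∂(output_t)/∂(feature map) at the final convolutional stage, the map is
the rectified weighted channel sum, normalized by its maximum — an
all-zero map stays zero rather than becoming 0/0 — and bilinearly
upsampled to the input resolution.  One map per view.  The convolutional
families support it; transformer attention rollout is out of scope.  On
zero-noise renders, a trained tiny conv model's mean heatmap intensity
over body pixels exceeding the background mean is the desk-scale analogue
of an expert judging anatomical plausibility.

Two properties of rectified regression CAMs are worth knowing.  First, the
rectification keeps only *positive* evidence for the target, so an animal
predicted below the mean can legitimately produce an all-zero map — the
evidence pushing its prediction down is discarded by the ReLU.  Second,
when part of the target signal enters through the tabular covariates, the
visual attribution only explains the residual and weakens accordingly.
The attribution plausibility check therefore trains the attention-fusion
model with the tabular branch disabled, forcing the prediction to rest
entirely on visual evidence — the same isolation the image-only ablation
variant provides — which yields body-focused maps on essentially all
held-out renders.

## Problem sizes used by the test suite

The suite trains tiny configurations — 64×64 or 32×32 renders, 2-layer
64-dim transformers, 4-block conv backbones, flocks of 24–150 animals, up
to 30 epochs — sizes chosen so the whole pipeline (generation, training,
statistics, explainability) demonstrates its contracts quickly on one CPU.
The calibration checks use a 10,000-animal flock.  Accuracy numbers
obtained at these sizes characterize the synthetic benchmark only.

## Known limitations

* The renders are geometric caricatures; no claim about real-image
  accuracy follows from any test here.
* The generator's dressing/bone/cap fractions are fixed per flock, so
  carcass weight is nearly proportional to live weight; real dressing
  percentages vary with condition and gut fill.
* Single-threaded determinism is part of the contract; parallel data
  loading would relax bit-reproducibility to statistical reproducibility.
* The transformer family has no built-in attribution method; Grad-CAM is
  defined only for the convolutional families.
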