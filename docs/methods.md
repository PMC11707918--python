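# Methods

This note documents the models, numerical choices and limitations of
`bcdnet` the way a maintainer would want them written down: what is
computed, why the defaults are what they are, and what passing the test
suite does and does not establish.

## The two-phase tuning problem

The pipeline classifies breast-ultrasound images into normal / benign /
malignant. Its learnable surface is deliberately split into a cheap
gradient-trained part (the two classifier branches) and a black-box
part handled by a population metaheuristic:

* **Phase 1** tunes a gain vector `g ∈ [0,1]^G` (G = 6, matching the
  optimizer's chromosome length) over contiguous groups of the deep
  feature columns, minimizing `Oj₁ = 1/acc` of a proxy classifier.
* **Phase 2** tunes four classifier hyperparameters — hidden widths
  `∈ [5,255]` and steps-per-epoch `∈ [10,50]` per branch — minimizing
  `Oj₂ = 1/acc + 1/MCC + FNR` on a stratified validation fold.

`1/MCC` is undefined or misleading for MCC ≤ 0; both reciprocals are
clamped at ε = 1e-6, so a degenerate classifier receives a large but
finite penalty (~1e6) and the objective's exact minimum, 2.0, is
attained only by a perfect classifier.

## The metaheuristic

### Switching rule

`RR = u / max_iter` at iteration `u`. The update branch is AOSMA when
`RR` is divisible by `switch_divisor` (default 0.02), else ESOA.
Divisibility is decided in integer arithmetic — `(u · round(1/d)) mod
max_iter == 0` whenever `1/d` is integral — because `RR` is a ratio of
integers and float modulo misfires on values like 0.06. A float
fallback with relative tolerance 1e-9 covers non-integral `1/d`.

Two consequences are worth stating plainly:

* at the default budget `max_iter = 50`, every `RR` is a multiple of
  0.02 and the hybrid reduces to pure AOSMA (logged at run time);
* at `max_iter = 100`, odd iterations go to ESOA and even to AOSMA.

Both schedules are asserted by enumeration in the tests. `RR` is
deterministic despite the family name suggesting randomness; no hidden
random draw is introduced.

### AOSMA branch

The slime-mould update in its standard published form: candidates are
sorted by fitness; log-scaled weights amplify the better half and damp
the worse half; the vibrate coefficient `vb ~ U(-a, a)` with
`a = arctanh(1 - u/T)` and the approach coefficient `vc ~ U(-b, b)`
with `b = 1 - u/T` shrink over iterations; with probability z = 0.03 a
candidate restarts uniformly in the box. The adaptive-opposition step:
a candidate whose move did not improve its fitness also evaluates the
box-mirrored point `lower + upper - x` and keeps the better of the two.
Opposition is an involution fixing the box midpoint (property-tested).

### ESOA branch

Per candidate, three proposals with greedy acceptance:

1. *sit-and-wait*: a pseudo-gradient `ĝ = (x - x*)(f(x) - f(x*)) /
   (‖x - x*‖² + ε)` is smoothed by exponential accumulators with decay
   rates β₁ = 0.9 and β₂ = 0.99 (first and second moment, bias-
   corrected), and the candidate steps along `-m̂/√v̂` with a step size
   `0.1·range·exp(-u / (0.5·T))`;
2. *aggressive*: a heavy-tailed tangent walk `x + tan(θ)·range/(1+u)`,
   `θ ~ U(-π/4, π/4)` per dimension;
3. *discriminant*: a uniform sample in a box around the global best
   whose half-width shrinks linearly to `range/T`.

The best proposal replaces the candidate only if it improves. The β
parameters live in the optimizer configuration; they are unrelated to
the Adam trainer's betas (below), which keep their own conventional
defaults.

### Shared mechanics

Positions are clipped to the box after every move (a reflected mode is
not provided; clipping is the simplest contract and the search spaces
here are well-scaled). Dimensions flagged integer are carried as
continuous values and rounded to the nearest in-bounds integer only
when the objective is called, keeping both update rules' real-valued
arithmetic intact. Objective values are memoized per exact rounded
position within a run — essential in phase 2, where one evaluation
trains two networks. An objective that raises or returns a non-finite
value contributes +inf (the candidate effectively keeps its position);
the error is counted and logged.

On the 6-D sphere in [-5,5]⁶ with the default budget (population 10,
50 iterations), AOSMA and the hybrid reach the optimum to ~1e-16 in
essentially all seeded runs and ESOA reaches a median of ~1e-2; the
acceptance suite pins these at ≤1e-2 (hybrid, ≥90 % of 20 runs) and
≤1e-1 (single branches, median).

## Feature extraction

The backbone is a fixed (non-trained) stack of 3×3 same-padded
convolutions with ReLU and 2×2 pooling, followed by a fully-connected
feature layer. Two profiles:

* **full** — the 13-convolution VGG16 layout, 224×224 input, 4096-wide
  feature layer, max pooling, ReLU on the feature layer; intended for
  use with externally supplied trained weights (`pretrained=True` with
  a `weights_path` .npz). The printed input size is 224: that is the
  defining VGG16 geometry.
* **tiny** — two small blocks (8 and 16 channels), 64×64 input,
  64-wide feature layer; the test-suite backbone, seeded-random.

A deliberate deviation in the tiny profile: **average** pooling and a
**linear** feature projection. With untrained random filters, max
pooling over speckle texture amplifies noise and a ReLU on a random
projection simply discards half the projected information; both choices
measurably destabilized the feature quality across seeds (nearest-
centroid transfer accuracy 0.55–0.95 with max/ReLU vs 0.95–1.00 with
avg/linear). With trained weights the conventional max/ReLU remain the
default. Both knobs are explicit config fields (`pool_mode`,
`fc_activation`).

Gains are applied as a per-group column multiplication. The grouping is
contiguous equal-width blocks — the simplest total partition; nothing
in the pipeline depends on group semantics. Note that the classifier
standardizes features with training statistics, which cancels any
*uniform* rescaling; gains act on the classifier mostly as soft feature
selection (a zeroed group stays zero), while the nearest-centroid
phase-1 proxy sees them at full strength.

The phase-1 proxy is a closed-form nearest-centroid classifier, written
in-package: it must return a finite accuracy even for the degenerate
all-zero-gain candidate (every centroid coincides; ties resolve to the
lowest class id), which library implementations reject. Its accuracy is
averaged over five seeded stratified 80/20 splits: the proxy is
closed-form, so the extra splits are nearly free, and a single small
fold lets degenerate gain vectors tie at the perfect score and win by
luck.

## The classifier (AHDNAM)

The flat feature vector (width F, 64 in the tiny profile) is treated as
a single-channel sequence of length F — the field's 1-D operators then
apply directly.

**DTCN branch**: ASPP (one branch per dilation rate 1/2/4: depthwise
separable dilated convolution, batch norm, ReLU; concatenation;
pointwise fusion to 16 channels) → four causal residual blocks with
dilations 1, 2, 4, 8 (two dilated convolutions with ReLU between,
pointwise skip projection where channel counts differ, ReLU after the
sum) → last-position features → dense(hidden) → ReLU → dense(classes) →
softmax. Four levels rather than three: with kernel 3, dilations
1+2+4+8 give a receptive field of ~61 positions, just covering the
64-long desk sequence; three levels (~29) leave the first half of the
feature vector invisible to the last-position readout.

**1DCNN branch**: convolution (32 channels, kernel 3, same-padded) →
ReLU → max-pool 2 → softmax attention over positions (a learned
projection scores each position; the attended weighted sum is the
sequence summary) → dense(hidden) → ReLU → dense(classes) → softmax.

Predictions are the elementwise mean of the two branch probability
vectors; argmax ties resolve to the lowest class index.

Training is plain Adam (lr 1e-3, β = 0.9/0.999) on softmax
cross-entropy, with exactly `steps_per_epoch` minibatch updates
(batch 16, sampled without replacement per step by a seeded generator)
per epoch for 5 epochs. "Steps per epoch" is the knob the optimizer
tunes in [10, 50]; the epoch count is fixed so the total gradient
budget stays desk-scale. All layers, initialization and backprop are
implemented in numpy inside the package (`bcdnet._nn`); gradients are
verified against central finite differences in the tests.

The phase-2 objective trains both branches on ⅔ of the training data
and scores the remaining ⅓. A third rather than the more common fifth:
at desk scale a 12-sample fold saturates (many candidates tie at the
objective floor 2.0) and the search degenerates into noise. For the
three-class problem the confusion counts feeding `Oj₂` are pooled
(micro) one-vs-rest counts, so the objective tracks overall accuracy
while still penalizing misses; for binary problems the positive class
is used directly.

## Metrics

All measures use the standard textbook definitions over the confusion
counts (TP, TN, FN, FP): accuracy, sensitivity/recall, specificity,
precision, NPV, F1, MCC, FNR, FPR, FDR, false-omission rate. Any 0/0
ratio is reported as 0 and flagged; a zero MCC denominator yields MCC
0. Multi-class evaluation is macro-averaged one-vs-rest, with the
malignant class as the headline positive (the clinically costly miss).
ROC curves sweep thresholds over the unique scores, group ties at one
threshold, and integrate by the trapezoid rule. Everything is checked
against brute-force per-sample loop oracles, exactly for the ratios and
to 1e-12 for MCC.

## Synthetic phantoms

The generator emulates exactly the statistics the pipeline needs and no
more:

* background: base intensity 0.55 ± 0.02, plus a smoothed Gaussian
  field (amplitude 0.05, correlation length ~size/10);
* benign: centered ellipse (radii 0.13–0.18 of image size, near-regular
  margin, boundary perturbation 0.04), intensity drop 0.7 ×
  `lesion_contrast`;
* malignant: larger ellipse (0.21–0.28), spiculated margin (radial
  perturbation `irregularity` = 0.35 with 6–9 lobes), full
  `lesion_contrast` drop (default 0.4) — so the classes differ in
  margin regularity, size and depth of hypoechogenicity, the cues
  radiologists actually use;
* speckle: clipped multiplicative Gaussian `pixel·(1 + σ·N(0,1))`,
  σ = 0.12 by default; a Rayleigh-derived variant sits behind
  `speckle_model="rayleigh"`. No acoustic physics (no depth-dependent
  attenuation, no log compression, no shadowing) is simulated.
* images are quantized to the 8-bit grid at generation time, making the
  PNG round trip bit-exact.

At the defaults a raw-pixel nearest-centroid baseline separates the
classes at ≥0.8 held-out accuracy — the floor the rest of the pipeline
must clear to demonstrate end-to-end recovery. Passing on phantoms
shows the pipeline's plumbing, optimization and training behave
correctly; it says nothing about clinical performance on real
ultrasound, where lesions are off-center, backgrounds structured, and
class overlap genuine.

Masks exist only as generation metadata; no `_mask` PNGs are written
(the loader's mask filtering is tested with synthetic mask files
instead), and the loader maps class folders to ids alphabetically.

## Profiles, determinism, limitations

* **desk** profile: 80 phantoms (27/27/26) at 64×64, tiny backbone,
  optimizer budget 4×5 per phase — the scale of the test suite and of
  `scripts/acceptance.py` (a run takes ~1.5 minutes on one core).
  **paper** profile: population 10, 50 iterations, 224×224 full
  backbone.
* Every stage derives its generator from the run seed; re-running any
  stage with the same config reproduces byte-identical arrays. The
  report writer re-derives the headline metrics from the persisted
  predictions and refuses to write an inconsistent report.
* Known limitations: the desk-scale accuracy estimates carry ±0.05
  granularity (20 test samples); the 1DCNN branch is the weaker of the
  two and occasionally sits near chance on a bad seed (the branch
  average is what the pipeline reports); hyperparameter selection on
  ~27-sample validation folds remains noisy even at ⅓ fraction — both
  phases improve the objective they optimize, but single-seed test
  accuracy can move either way relative to untuned defaults.
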