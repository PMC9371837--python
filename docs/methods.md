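# Methods

This note documents the models and procedures `brainfuse` implements, the
parameters that matter, the numerical conventions, and what the synthetic
study conditions do and do not establish.

## Wrapper selection over a continuous relaxation

Both selectors search the box [0, 1]^d; a candidate position **x** decodes to
a feature subset by `selected[j] = x_j > 0.5`. If no coordinate clears the
threshold, the single largest coordinate is selected (first index on ties),
so the subset is never empty. The subset width is therefore emergent — the
two selectors generally return different widths, and the fused width is their
sum.

**Objective.** The fitness of a subset is the misclassification rate of a
1-nearest-neighbour classifier (Euclidean distance, exact ties broken by the
lowest training-row index) restricted to the selected columns. Columns are
z-scored with training-split statistics before distances are computed
(zero-variance columns get unit scale). By default the error is averaged
over 3 stratified 70/30 holdout splits; a stratified k-fold scheme is
available by config. Averaging over repeated holdouts damps split noise so
the selectors optimize a more stable objective at modest cost; the splits
depend only on the labels and the fitness seed, never on the selector's own
random stream, which keeps selector trajectories exactly replayable.

**Differential evolution.** Initialization draws every coordinate uniformly
within its bounds. Per generation, each target i receives a rand/1 donor
ν = x_{r1} + F·(x_{r2} − x_{r3}) with r1, r2, r3 distinct and ≠ i, clipped
to bounds; binomial crossover takes the donor coordinate where a uniform
draw ≤ Cr or at the forced coordinate j_rand; the trial replaces the target
iff its error is ≤ the target's (greedy, elitist). Defaults: population 50,
F = 0.2, Cr = 0.7, 50 generations. The population-best trace is
non-increasing by construction.

**Particle swarm.** Positions initialize uniformly, velocities at zero.
Updates are synchronous: all particles move using the global best from the
previous evaluation, v ← ω·v + C₁·r₁⊙(lb − x) + C₂·r₂⊙(gb − x) with
independent uniform draws per coordinate, clamped to ±0.5·(bound range),
then x ← x + v clipped to bounds; personal bests update on strict
improvement and the global best is the best personal best. Defaults:
population 50, ω = 0.7, C₁ = C₂ = 2.0, 50 generations. The global-best
trace is non-increasing by bookkeeping.

**Random-stream contract.** Each run consumes a single seeded
`numpy.random.Generator` in a documented order (init block, then per
generation: DE — index triples, j_rand, crossover draws; PSO — cognitive
then social draws per particle). The test suite replays this stream in
independently scripted step-by-step oracles and requires agreement to 1e-12.

**Termination.** Fixed `max_generations`, with an optional early stop after
a configurable number of generations without improvement (off by default).
"Optimal" here means best-found under the budget; the selected widths are
stochastic outcomes, not targets.

## Serial fusion and PCA

Serial (serial-based extended) fusion concatenates two blocks over the same
samples: rows must align exactly (equal label vectors), K = Y + Z, feature
ids are prefixed by block id. The DE block comes first, then PSO.

PCA is fit by thin SVD of the mean-centered matrix; explained variances use
the unbiased (N−1) normalization, and each component's sign is fixed so its
largest-magnitude loading is positive, making the fit deterministic.
Centering only — no per-column rescaling — since the evaluation harness
standardizes per training fold anyway. `k` is an explicit integer
(capped at min(N−1, K)); at the method's native scale the convention is
k = 1000 out of a fused K ≈ 2244, and the desk-scale analogue used in the
examples and the acceptance script is k = 20 out of K ≈ 60, chosen to keep
the same character (a ~3× reduction that retains the high-variance
structure). Inside cross-validation, PCA (like standardization) is fit on
the training fold only and applied to the held-out fold, so no test
information leaks into the projection — a deliberate convention even where
the fold-external alternative would be simpler.

## Backbone and transfer learning

The feature extractor is a ResNet-style bottleneck network implemented
directly on numpy (im2col convolutions, stored-statistics batch-norm, global
average pooling). The `resnet101` registry entry reproduces the standard
stage plan [3, 4, 23, 3] and emits the 2048-wide pool5 descriptor; a
`resnet_micro` entry (stages [1, 1], width 32) exists for fast runs. Weights
initialize with seeded He draws; `pretrained=True` loads a local `.npz`
checkpoint and never downloads.

Transfer learning is head-retraining: the convolutional body is a frozen
feature extractor and the classification head — a softmax layer on pool5 —
is trained by mini-batch SGD with momentum under cross-entropy. Two named
presets reflect the two plausible settings for this step: `paper-s3`
(lr 1e-4, batch 32) and `paper-s4` (100 epochs, lr 0.05, momentum 0.7);
the transfer default is lr 1e-4. Head-only training keeps every contract
testable at desk scale (loss trends, zero-lr identity, seeded
reproducibility) and is the package's deliberate reading of "retraining" a
pretrained model on a small target set; it does not reproduce GPU-scale
full fine-tuning, which is out of scope.

Image preprocessing: grayscale slices replicate across three channels
*before* normalization, bilinear resize to 224×224, and either scale-to-[0,1]
(default) or the ImageNet per-channel mean/std preset. The blank-frame
filter removes slices whose maximum intensity is ≤ a threshold (default 0,
i.e. strictly all-zero — the conservative reading of "totally black").
It is idempotent and order-preserving.

## Classifier bank and metrics

The nine presets are translations of the common MATLAB Classification
Learner presets to scikit-learn estimators: fine tree → decision tree with
at most 100 splits; linear discriminant → LDA; cubic SVM → SVC with a
degree-3 polynomial kernel; boosted trees → AdaBoost on shallow trees;
bagged trees → random-forest bagging; subspace discriminant → a random-
subspace ensemble of LDA learners; narrow/medium/wide NN → single-hidden-
layer perceptrons with 10/25/100 units. Exact MATLAB hyperparameters are
not knowable; every preset is overridable.

Evaluation pools out-of-fold predictions from stratified k-fold (default 10)
into one confusion matrix per classifier. Metrics are unweighted macro
averages of per-class one-vs-rest ratios: sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), FPR = FP/(FP+TN), FNR = 100 − sensitivity (so
sensitivity + FNR = 100 holds exactly, by construction). Accuracy,
sensitivity, FNR and precision are percentages; FPR and AUC are fractions —
mixed units, but the reporting convention of this literature. AUC is the
unweighted mean of per-class binary ROC areas computed from pooled
out-of-fold scores (predicted probabilities where available, decision
values otherwise). A class with a zero denominator contributes 0 and is
listed under `degenerate_classes`. Prediction time (total wall time of the
predict calls) is reported for parity but never asserted — it is hardware-
dependent.

## Synthetic study conditions

`make_feature_fixture` plants exact structure: informative columns are
class-conditional Gaussians whose class means are random unit directions in
the informative subspace scaled to `class_sep`, with isotropic `noise_sd`
noise; redundant columns are linear copies of informative ones plus noise
(sd 0.3); remaining columns are standard normal. Defaults: 4 classes × 50
samples, d = 60, 8 informative, 8 redundant, class_sep = 4.0, noise_sd = 1.
The separation was calibrated once, at design time, so the fixture exhibits
the landscape wrapper selection exists for: an informative-only mask reaches
near-Bayes error (~3–5%), the all-features mask is measurably degraded by
noise columns (~15–20%), and a noise-only mask sits near chance (75%). With
those defaults both selectors recover most planted informative columns and
beat random same-size masks by a wide margin.

`make_image_fixture` draws per-class ellipses (class-specific radius,
eccentricity and intensity) on dark background with half-normal noise,
240×240 grayscale by default, and plants an exact count of all-zero frames
(`blank_fraction`, round-robin over classes) whose ids are returned as
ground truth.

What passing on these fixtures shows: the update equations, decoding,
fitness, fusion algebra, PCA, metric identities and end-to-end determinism
are correct, and the selectors genuinely concentrate on informative
structure. What it does not show: behaviour on real multimodal MRI — real
deep features are correlated in ways Gaussian blocks are not, class
structure is not isotropic, and the reported classifier accuracies and
prediction-time ratios of the method's native application do not transfer
from this scale.

## Numerical conventions and degenerate inputs

- 1-NN ties: lowest training-row index. Decode ties: first index.
- DE replacement uses ≤ (accepts equal-fitness trials — drift along
  plateaus); PSO personal bests use < (strict improvement).
- Bounds are enforced by clipping after every mutation/velocity update.
- Zero-variance columns standardize with unit scale instead of dividing by
  zero; empty feature blocks fuse as identities; an all-below-threshold
  position still decodes to a non-empty subset.
- Per-stage seeds derive from the global seed by stage-name hashing
  (CRC32 XOR), kept below 2³¹.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
n = 200 samples, d = 60 features, selector populations 50 × 50 generations,
10-fold evaluation, PCA k = 20. These sizes preserve every structural
property of the method (the 2048-wide extraction path is exercised
separately through the backbone contracts) while keeping a full run in
seconds to minutes on one CPU.

## Known limitations

- The backbone trains only its classification head; there is no autodiff
  through the convolutional body.
- `pretrained` requires a user-supplied checkpoint; no public weights are
  bundled.
- MATLAB classifier presets are translated, not emulated; absolute
  accuracies on a given dataset will differ from MATLAB's.
- Prediction-time speedups are reported, never asserted or reproduced.
- The NIfTI loader slices along the last axis only and treats per-class
  folders as the class mapping; it does not parse BraTS directory metadata.
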