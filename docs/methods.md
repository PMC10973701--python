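# Methods

## Overview

`capspace` models how high-level spatial structure can be extracted from
simple visual displays. The centerpiece is an unsupervised capsule
autoencoder ("U-CapsNet") trained to reconstruct spatial-working-memory
(SWM) stimulus images — arrays of 1, 3, 5 or 7 yellow circles around a
central fixation cross — and a battery of representational analyses that
compare its internal features, hand-defined spatial features, and
multi-subject brain-like activation tables with a planted ground truth.
Real neuroimaging data is out of scope; the synthetic-brain generator
stands in for it so that every statistical procedure in the package is
exercised against a known answer.

## Stimuli

Each of the 48 trials pairs a target array (yellow circles) with a probe
(one green circle): 12 trials per set size, 4 per set-size-by-delay cell
(delays 1.5 / 3 / 4.5 s), half true-positive (probe reuses a target
position exactly) and half true-negative (probe at least `d_min` pixels
from every target). Images are rasterized natively at 30x30 RGB with
intensities in [0, 1]; the original displays were larger and downsampled
to 30x30 before modeling, and generating natively at that size is
equivalent post-resize. The model training set is 400 additional images
(100 per set size) of yellow circles on black, without a fixation cross.

Unstated display parameters were fixed once as package defaults: circle
radius 2 px (the largest radius at which 7 mutually non-overlapping
circles place reliably on a 30x30 canvas with margin), fixation cross a
3-px white "+" at the canvas center, yellow = (1,1,0), green = (0,1,0),
`d_min` = 2*radius + 1 px. Placement is rejection sampling capped at
10,000 attempts (then an error), with circles fully on canvas, pairwise
center distance > 2*radius, and a clearance zone around the fixation.
Coordinates are 0-based pixels with y measured upward, so the origin used
by the distance features is the bottom-left corner.

## Hand-defined spatial features

Spatial location features (SLFs): circle counts per 90-degree quadrant
around the fixation plus the unweighted centroid of circle centers.
Quadrants are anchored at the fixation; a center exactly on an axis is
assigned to the counter-clockwise-adjacent quadrant (a deterministic tie
rule — ties occur with probability zero under the sampler but matter for
hand-constructed inputs). Spatial distance features (SDFs): mean distance
to fixation, mean distance to the origin, and mean pairwise inter-circle
distance, defined as 0 for a single circle. Both are computed exactly
from the generating circle specifications, never from pixels. The
abstract "VFN & SFN" descriptor is the 3-vector of L2 norms of (a) the
image's principal-component scores (PCA fitted on the training images;
components retaining 95% variance by default), (b) the SLF vector, (c)
the SDF vector.

## The capsule autoencoder

Encoder: Conv(3->256, kernel 9, stride 1) + ReLU giving Layer 1
(256x22x22); Conv(256->640, kernel 9, stride 2) reshaped into a 64x7x7
grid of 10-dimensional primary capsules (3136 capsules, Layer 2), each
squashed; dynamic routing from all primary capsules to a single
40-dimensional higher capsule (Layer 3). The 30->22 and 22->7 spatial
maps force kernels 9/9 and strides 1/2 — the conv hyperparameters are
derived from the layer shapes, which are the fixed points of the design.

Squashing: `v = (|s|^2 / (1 + |s|^2)) * s/|s|`, zero maps to zero, norms
strictly below 1. Routing: priors `b` start at 0 each forward pass; each
round computes coupling coefficients by a softmax of `b`, the weighted
sum `s_j`, the output `v_j = squash(s_j)`, and the agreement update
`b_ij += u_hat_ij . v_j`. The softmax is normalized **over the lower
capsules** by default; the classic convention (over higher capsules) is
available by configuration but is degenerate with a single higher capsule
(all coefficients 1). Three routing iterations by default.

Decoder: a fully connected layer maps the higher capsule to a 64x7x7
tensor, followed by three transposed convolutions (7->14->28 with kernel
4 / stride 2 / padding 1, then 28->30 with kernel 3 / stride 1), sigmoid
output. The decoder widths (64, 32, 16) were chosen to invert the encoder
geometry at comparable scale; they are free parameters of the design.

Training minimizes mean absolute error (per pixel, per channel, averaged
over the batch) with Adam at learning rate 1e-4. Parameter initialization
and batch shuffling are fully determined by the seed. Full-batch training
is the default; a `batch_size` argument trades peak memory (the im2col
buffers of the primary-capsule convolution dominate) against nothing
else — the loss is a running mean over batches either way.

The networks run on an in-package reverse-mode automatic-differentiation
engine over numpy arrays (`capspace.autodiff`): a tape of tensor nodes
with convolution/deconvolution expressed as im2col/col2im matrix products
so training runs at BLAS speed on one CPU. Gradients of every operation
are verified against central finite differences in the test suite, and
the convolutions against independent loop/scipy oracles.

### Problem sizes

The reference training protocol is 3000 epochs; the package's tests and
the acceptance script use scaled-down runs sized for a single CPU — 12
epochs (acceptance) and 2 epochs (test suite) on the 400-image set, with
`batch_size = 50`. This is adequate for the Layer-1/pixel-space
representational comparison because that quantity is dominated by the
convolutional architecture (a bank of local linear filters + ReLU
approximately preserves pixel-space distances) rather than by converged
weights: at the default configuration the correlation moves by < 0.01
between initialization and several epochs of training. Conclusions that
depend on a converged latent space (e.g. reconstruction quality of
Layer 3) are exercised at the scaled-down architecture
(`capsnet.tiny_config()`), where training to convergence takes seconds.

## Control models

All controls consume the same 30x30x3 inputs, seeds and optimizer
protocol, so comparisons differ only in architecture and objective:

* **PCA pixels** — linear projection of flattened images, fitted on the
  training set.
* **VAE** — three-conv encoder (30->22->7->5, mirroring the capsule
  front-end's scale), linear head producing 40 latent means and 40
  log-variances, reparameterized sample, three-deconv decoder. Loss =
  MAE reconstruction + KL to a standard normal, with the KL averaged
  over batch *and* latent dimensions so both terms are on the same
  per-element scale ("unit weight" then means equal footing; a KL summed
  over dimensions would dominate the objective at this image size). The
  latent means are the control feature set.
* **SFF-CNN** — the same three-conv stack plus two linear layers, trained
  with cross-entropy on the circle-count class ({1,3,5,7} -> {0..3});
  features are the flattened third-convolution maps.
* **S-CapsNet** — the U-CapsNet encoder plus two linear projection
  layers, cross-entropy objective; features are the higher-capsule
  vector.

## Representational similarity analysis

RDMs are built at the image level: Euclidean distance for model features
and hand features, correlation distance (1 - Pearson r between patterns)
for activation tables. Comparisons correlate the strict upper triangles —
Spearman when a hand-feature RDM is involved, Pearson between
computational models and brain-like tables. Condition-subset analyses
(by memory load, delay, probe truth) subset RDM rows/columns, which is
exactly equivalent to building the RDM from the subset's features.

Significance: condition-label permutation tests (jointly permuting rows
and columns of one RDM, 1000 permutations by default) with the add-one
p estimator `p = (1 + #{null >= obs}) / (1 + n_perm)`; the stricter
"observed exceeds the null maximum" criterion is reported as a separate
boolean rather than folded into the p-value. Noise ceilings: upper bound
= mean correlation of each subject's RDM with the group mean; lower
bound = the same against the leave-one-subject-out mean. Behavioral
analysis correlates per-subject model-brain similarity with response
accuracy (Pearson), Benjamini-Hochberg-adjusted across ROIs; r values
are averaged raw (not Fisher-transformed) when aggregating over regions.

## Encoding models

Features are PCA-reduced to the smallest number of components whose
cumulative explained variance reaches 99% (PCA fitted on the 48 analysis
conditions themselves). Per voxel, ordinary least squares with an
intercept is evaluated by leave-one-condition-out cross-validation;
accuracy is the Pearson correlation between the assembled held-out
predictions and the actual series. Two conventions deserve note. First,
the per-fold intercept is estimated but *excluded* from the assembled
prediction series: Pearson accuracy is location-invariant, and the
intercept tracks the training-fold mean, which is anti-correlated with
the held-out value — including it drives the null expectation of the
accuracy strongly negative (to exactly -1 for an intercept-only model).
With slope-only assembly the null accuracy is centered near zero at the
design sizes the 99% criterion actually produces (about 10-30 regressors
for 48 conditions), which is what a calibrated accuracy should do.
Second, response-stage encoding concatenates the stimulus-image and
probe-image feature rows trial-wise before the PCA.

## Mediation

Given aligned RDM triangles for an independent variable (hand features),
mediator (model features) and dependent variable (brain-like activation,
averaged over regions then subjects), two OLS regressions estimate
`Med = a*IV` and `DV = b*Med + c*IV`. Intercepts are included — the
textbook mediation equations omit them, but distance vectors are not
centered and forcing the fits through the origin would bias every slope.
Inputs are standardized by default so a, b, c are comparable. The
indirect effect is tested with the Sobel statistic
`t = ab / sqrt(b^2 se_a^2 + a^2 se_b^2)` against a standard normal at
alpha = 0.001; complete mediation = Sobel significant while the direct
path c is not, at the same alpha. A mediator numerically collinear with
the IV is rejected rather than silently fitted.

## Representational change

The change of representation between two systems is the difference of
their z-scored RDMs, z-scoring the strict upper triangle only (the zero
diagonal would otherwise deflate the variance estimate; the triangle
carries all the information of a symmetric RDM). "Change from X to Y"
means `z(RDM_Y) - z(RDM_X)`. A model change-RDM (capsule vectors vs
capsule norms) is correlated (Pearson) with region-pair change-RDMs per
subject, with permutation p-values; a region pair is flagged when at
least 90% of subjects are individually significant at p < .05.
Z-scoring makes the analysis invariant to any affine transform of either
underlying RDM, which the tests assert numerically.

## Synthetic brain

`simulate_region` plants a target correlation-distance RDM `D` into a
condition-by-voxel pattern matrix exactly: the target correlation matrix
`C = 1 - D` is factored `C = X X^T` (eigendecomposition; small negative
eigenvalues are clipped and reported, and a Frobenius residual above 5%
of the spectrum raises an embedding error), and `X` is expanded into
voxel space by a random orthonormal basis with zero-mean columns — the
orthonormality makes the sample covariance of the patterns reproduce
`C`, and the zero-mean columns eliminate the sample-mean corrections, so
at mixing weight 1 and zero noise the observed RDM equals the target to
numerical precision. Mixing weight `lambda` interpolates toward an
independent random geometry, and white voxel noise is added on top.

`simulate_cohort` draws per-subject lambda offsets (sd 0.15 by default)
so subjects vary in how faithfully they express the planted geometry;
per-subject accuracy is a logistic function (intercept 1.4 ~ 80%
baseline accuracy, slope 0.5) of the standardized planted model-brain
similarity plus accuracy noise (sd 0.02), giving the behavior analysis a
recoverable planted association. Default regions are labels only
(frontal, ventral, dorsal, early visual, hippocampus), 60 voxels each,
activation noise sd 0.3 — chosen to put subject RDM fits in a realistic
0.3-0.8 range rather than at ceiling. What this generator deliberately
does **not** emulate: temporal autocorrelation and drift of fMRI noise,
spatial smoothness across voxels, atlas geometry, or any volumetric I/O.
Passing tests therefore demonstrate the *statistical machinery* recovers
planted structure at realistic SNR, not that real BOLD data would behave
this way.

The GLM mirror builds trial-wise boxcar regressors from the paradigm
timeline (2 s target array, the trial's delay, 3 s response window, 2 s
inter-trial fixation), convolves them with the canonical double-gamma
hemodynamic response (peak 6 s, undershoot 16 s, peak:undershoot ratio
6), samples at TR = 2 s, adds white noise, and re-estimates the betas by
OLS — zero noise recovers them to machine precision, and the error
scales linearly in the noise sd.

## Pipeline

`pipeline.run_all` chains every stage and writes a JSON + TSV report.
All randomness derives from the master seed through named substreams;
the expensive training/extraction stage is cached on disk keyed by a
hash of the fields that determine it, so re-running downstream stages
reproduces the full-run outputs bit for bit. The synthetic cohort plants
capsule-layer geometry in the associative regions and capsule-norm
geometry in the dorsal-stream regions, so the mediation,
representational-change and behavior stages have recoverable structure.

## Numerical choices and degenerate inputs

Squash guards the zero vector explicitly (autodiff path: an epsilon of
1e-9 inside the inverse norm, which perturbs norms by < 1e-8). Softmax
subtracts the rowwise maximum. RDM metrics reject zero-variance rows
(correlation distance) and constant triangles (comparison, z-scoring)
with informative errors instead of NaNs. PCA on a degenerate
(zero-variance) training set is flagged rather than refused. LOOCV
raises on rank-deficient designs with advice to lower the variance
target. Permutation p-values use the add-one estimator and so can never
be 0. All trained-model determinism is bit-exact for a fixed seed on a
fixed BLAS.

## Known limitations

* Scaled-down training: the default-seed acceptance run trains for 12
  epochs, not 3000; only architecture-dominated quantities are claimed
  at that budget.
* The decoder and control-model layer widths are package choices; only
  the encoder shapes are externally fixed.
* The routing softmax orientation in the original work is ambiguous;
  both conventions are implemented, `over_lower` being the default.
* The synthetic cohort's noise model is white and Gaussian; effect sizes
  measured on it do not transfer to real fMRI.
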