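# Methods

This note documents the models and procedures implemented in `lsdm`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions a user should know about.

## The layered searchlight

A locally connected layer `H` applies overlapping cubic kernels of size `k`
(stride 1, valid padding) with *independent* learnable weights at each output
location — a packaging of many separate linear maps that still shares
intermediate computations between neighboring locations.  Stacking `L` such
layers gives every final location a receptive field of `L·k − L + 1` voxels
per axis; with the defaults `k = 2, L = 4` each output location is a
classifier over a 5×5×5-voxel patch.  Channel widths run
`c_in → ch → ch → ch → n_classes` with `ch = 3` (three latent channels per
location, matched to the dimensionality needed for a circular stimulus
geometry plus a luminance axis).  Batch normalization with independent
statistics per (location, channel) is applied between layers (momentum 0.1,
eps 1e-5; evaluation uses running estimates).  No nonlinear activation is
used by default, so at evaluation time each patch computes an affine function
of its receptive field; ReLU and dropout are available as options.  Filters
are initialized from a zero-mean Gaussian with variance `1/fan_in` under a
recorded seed.

Setting `k = 5, L = 1` reproduces a bank of standard multinomial logistic
searchlights exactly (the baseline module is implemented through the same
engine, so the two training paths are bit-identical in that configuration).
Per-patch parameter counts at 12 classes and one input channel: standard
`(125 + 1)·12 = 1512`; layered ≈ 567 (total parameters divided by the number
of patches).

### Objective

Classes are 12 = 6 hues × 2 luminance levels, split into counterbalancing
sets A and B with alternating hues.  Softmax, cross-entropy and accuracy are
evaluated only within the true label's (set, luminance) group of 3 classes
(chance 1/3); the latent space is shared across all classes.  Argmax ties
break toward the lowest class index.  Training oversamples every class to
the majority count (after the train/test split, never on test data) and
weights the per-class loss by `w_b ∝ (1 − acc_b) + 0.05`, normalized to mean
1, where `acc_b` is an exponential moving average (weight 0.5) of the class's
training accuracy — classes the model currently finds hard get more weight.
This inverse-accuracy rule is one reasonable instance of difficulty-based
reweighting and is pluggable.

### Training protocol

Adam (lr 1e-3 by default), minibatches, fixed maximum epoch budget (120).
Epoch selection uses a validation split: 12.5% of the *training* trials are
held out (never test data), and training stops when the mean within-group
patch accuracy on that split has not improved for 10 epochs; the best-epoch
weights are restored.  We chose validation stopping over a training-loss
plateau because for both architectures the training loss keeps falling deep
into the overfitting regime at realistic dataset sizes, so a loss plateau
either never triggers within budget or triggers far past the test-accuracy
peak.  With `val_fraction = 0` the engine falls back to a training-loss
plateau rule.  Training is deterministic given the config seed; divergent
(NaN) losses raise with diagnostics rather than continuing.

Voxels outside a brain mask are zero-filled and a patch is kept if its
center voxel is inside the mask; with even `k` the stacked receptive field
is odd-sided (5³ at defaults) and the patch is assigned to its geometric
center voxel.

## Stacking weights and ROI accuracy

The naive ROI accuracy (mean over member patches) is diluted by
uninformative patches.  Instead a single probability distribution `w` over
patches is fit by maximizing the within-group log-likelihood of the stacked
distribution `c* = Σ_i w_i c_i`, with `w = softmax(θ)` and deterministic
full-batch adaptive gradient ascent (the likelihood is not concave in θ, so
the result is an approximate maximum-likelihood solution; in practice the
weights concentrate sharply on informative patches).  Restricting to an ROI
renormalizes `w` over the member patches — the maximum-likelihood solution
for that subset — and argmax of the ROI's `c*` within the true label's group
gives one accuracy per ROI.  Weights are fit per training fold, on the
training folds' predictions only, which keeps the held-out fold untouched; a
single set fit on all data would leak.

## Representational geometry

Latent states are the inputs to the final layer (evaluation-mode
normalization), three channels per location, taken from a model fit on data
disjoint from the trials being analyzed.  Per location, class embeddings are
the mean latent per class; `D_j` is the 12×12 matrix of Pearson correlation
distances between class embeddings (zero diagonal, entries in [0, 2]).  The
matrices feeding each final-layer filter are averaged over its `k³` input
locations (a uniform filter), and an ROI matrix `D_R` is the
stacking-weight-normalized convex combination over member patches.

The circular-rank correlation ρ ranks the 15 upper-triangle distances of the
light and of the dark 6×6 sub-matrix (fractional/average ranks for ties;
distances are rounded to 10 decimals first so float-identical values tie),
Pearson-correlates each with the canonical ranking of six evenly spaced
items on a circle, and averages the two.  ρ is invariant to monotone
transforms of the distances and to reversal of the circular ordering.  A
constant distance vector has no defined correlation and is flagged missing
(NaN), never reported as 0.

Significance uses a null over random orderings of six items (Monte Carlo,
default 10 000 draws, or exhaustive over all 720 orderings).  Because one ρ
averages the light and dark correlations, the matched null averages two
independent ordering draws; when several independent ρ measures are averaged
the null averages correspondingly more draws and the threshold shrinks.  A
second null that permutes the entries of the observed rank vector
(preserving its tie structure) is provided behind a switch; the two are not
assumed equivalent.

Classic voxel-space RSA is implemented for comparison: per-class mean
volumes, concatenated over a `k³` cube of voxels per patch (the cube sits at
offset `(receptive_field − k) // 2` from the patch anchor; `k = 1`
degenerates to single-voxel condition vectors), Pearson distances, then the
same stacking-weighted ROI average.  MDS plots use classical (Torgerson)
scaling — deterministic, identified up to rotation/reflection, negative
eigenvalues truncated at zero.

## Trial-wise GLM design

Each trial contributes three cue-TR *impulse* regressors (one TR each), one
cue HRF regressor (boxcar over the three cue TRs convolved with the
hemodynamic kernel, then **zeroed at every TR where one of that trial's cue
impulses is active**, so it only absorbs the delayed tail), and one choice
HRF regressor.  Discrete-cosine drift columns (all frequencies below the
cutoff, default 0.03 Hz, constant included) and user-supplied confound
columns (HRF-convolved) complete the design.  The hemodynamic kernel models
an intravascular contrast agent: a gamma-variate with shape 4.7 and scale
0.745 s, peaking at ≈2.76 s with FWHM ≈3.8 s, sampled at the requested
resolution and normalized to unit area; the functional form is fully
parameterized and a delta kernel is available for limit checks.  Polarity
(the contrast agent's signal decreases with activation) is left to the
caller.

Fitting is OLS, or exact AR(1)-prewhitened GLS: the lag-1 autocorrelation is
estimated per target from OLS residuals and both sides are transformed with
the exact AR(1) square root (first observation scaled by `sqrt(1 − ρ²)`)
before refitting.  Rank-deficient designs raise.  Decoder inputs are the
coefficient maps of the *second and third* cue TRs (two channels per trial);
the first cue TR carries little delayed signal and is excluded unless
explicitly requested.

## The synthetic validation data

Each example is a 16×16×16 volume with two 5×5×5 signal regions: upper-left
(UL, corner (1, 1, 6)) and lower-right (LR, corner (10, 10, 6)), both
centered on the middle of the third axis.  Class signal is circular +
high-dimensional:

* circular — the 6 same-luminance classes evenly on the unit circle,
  embedded in the region's 125 dimensions via a random orthonormal
  transform; dark classes offset by 1.0 along a random axis orthogonal to
  the circle plane.  In LR the circular signal is *shared* between
  associated shape (S) and color (C) classes; UL carries an independent
  circular signal for S only.
* high-dimensional — an orthonormal embedding of the 12 one-hot class codes,
  scaled by 1.5, drawn independently for (UL, S), (LR, S) and (LR, C), so it
  never transfers across modality.

Isotropic Gaussian noise with standard deviation 1.5 ("spread" is read as
SD) is added over the whole volume per example.  In the structured-noise
variant, one Gaussian vector with SD 0.3 is drawn per counterbalancing group
per modality and added to all of that group's examples — noise becomes
class-dependent through group membership; a per-example variant is available
behind a flag.  Ground-truth ROIs are the signal regions dilated by one
voxel (still disjoint).  Datasets are bit-reproducible from (config, seed).

What the generator does *not* emulate: temporal autocorrelation and
hemodynamics (the GLM module has its own time-series fixtures), spatial
noise correlations, anatomical variability, motion, or session structure.
Passing benchmarks on these volumes therefore validates the estimators and
their contracts, not performance on real scanner data.

### Benchmark protocol and problem sizes

The packaged study trains on the color (C) dataset, 8-fold cross-validation
stratified by class, and evaluates identity (held-out C) and cross-decoding
(matching S fold) through stacking weights in ROI 2, at 60 and 120 examples
per class.  Because every searchlight location is an independent model,
training is done on the ROI's bounding box padded by half a receptive field
— exactly equivalent to the corresponding locations of a whole-volume model
at a fraction of the cost; stacking weights renormalize over the ROI either
way.  Both architectures use the identical protocol (`lr 2e-3`, batch 120,
max 120 epochs, validation patience 10) so comparisons isolate architecture,
not tuning.

Chance thresholds match the quantity they gate: per-patch accuracy maps use
the pooled per-patch label-permutation null (1000 permutations, 95th
percentile); the cross-validated stacked ROI accuracy uses the null of the
*fold-mean stacked ROI accuracy* under per-fold label permutations; geometry
uses the 10 000-ordering null.

Geometry embeddings need many more trials per class than one held-out fold
contains at desk scale (a 12×12 Pearson matrix from ~7 trial means per class
is rank noise), so the geometry study evaluates each fold's model on an
*independent evaluation set* of 60 fresh examples per class drawn from the
same planted signals (and, in the structured case, the same per-group noise
offsets) with independent noise — disjoint from all training data by
construction, with offset trial ids so the leakage guards can prove it.

Observed behavior at these sizes: cross-decoding — the quantity that depends
on the *shared* circular signal — is reliably better under the layered model
than the standard searchlight, and latent-space geometry recovery is robust
to structured noise while classic voxel-space RSA collapses under it.  For
*identity* decoding the standard searchlight can match or exceed the layered
model at these dataset sizes: identity exploits the 12-dimensional
modality-private signal, which the three-channel bottleneck compresses; this
is a known limitation of the layered architecture in regimes where the
discriminative signal is genuinely high-dimensional, and the corresponding
benchmark assertion documents it rather than hiding it.

## Predictive-coding model

Two layers with symmetric binary weights `W` (features × concepts; each
concept binds one color and one shape).  Per discrete step with rate α
(default 0.2, chosen inside the empirically stable range):
`R_t = P_t − W C_t` (computed from pre-update states), `P_{t+1} = P_t +
α(I − P_t)`, `C_{t+1} = C_t + α Wᵀ R_t`.  The printed-shape convention is
kept (`W` is features × concepts, 5×3 in the worked example) and the
transposes are resolved by dimensional analysis.  The dynamics are linear
(superposition holds to 1e-10); with a complete-concept input the residual
decays toward zero, while an input missing a bound feature sustains residual
in the missing channel.

## Contrast statistics and bootstrap

Selectivity `(b₁ − b₂)/(b₁ + b₂)` flags voxels with `|b₁ + b₂| < 1e-12` as
missing.  The z contrast is `mean(diff) / sqrt(Σ var / n²)`.  Percent signal
change is `100·β / baseline`.  The multi-subject bootstrap concatenates all
subjects' examples and resamples with per-example probability
`1/(m·|D_i|)`, so each subject contributes equally in expectation; the 95%
CI is the 2.5–97.5 percentile band over 1000 iterations.  Calibration note:
with unequal subject sizes the effective sample size is below the total, so
the percentile CI under-covers slightly (≈93% at a 2:1 imbalance in our
checks) — the price of equal subject representation.

## Numerical engine

The locally connected layers, batch norm, and Adam are implemented directly
in NumPy with manual backpropagation (batched GEMMs over a leading location
axis; activations in location-major layout to avoid copies).  Gradients are
verified against central finite differences in float64 in the test suite.
All randomness flows through seeded `numpy.random.Generator` instances;
training, simulation and permutation results are reproducible bit-for-bit
on a fixed BLAS/thread configuration.
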