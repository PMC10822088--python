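# Methods notes

This note records the models implemented in `fearcond`, the assumptions
behind them, the defaults and the numerical choices, in the spirit of a
statistical-methods appendix. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Encoding model

Each neuron's trace, aggregated into 500-ms bins (mean within bin,
partial trailing bin dropped), is fitted by ordinary least squares to
lagged predictors: one autoregressive column (the trace lagged one bin),
trial-split binary indicators for tone, footshock and inter-trial
interval at lags 0…L−1 (kernel length L = 5 bins = 2.5 s by default), and
L lagged copies of speed, which is continuous and not split by trial. For
a 6-trial session this is 1 + 3·6·5 + 5 = 96 columns.

*Intercept.* The model equation carries no intercept, but a coefficient
of determination computed against centered total variance is only
guaranteed to lie in [0, 1] when one is present. The fit therefore
appends an intercept column internally; it is not a design column and is
retained — like the autoregressive column — in every reduced model.

*Incomplete lag history.* The first L−1 bins (which would need predictor
values from before the session) are dropped from the fit rather than
zero-padded, so no predictor values are fabricated.

*Structural rank deficiency.* Lagged trial-split dummies are not linearly
independent: a shock indicator lagged past the shock window lies inside
the ITI support, and with contiguous tone→ITI tiling plus truncation at
the session end this produces roughly one exact linear dependency per
trial (rank 91 of 97 for the default session). Fits use rank-truncated
SVD bases (equivalently the pseudoinverse, minimum-norm coefficients) and
record a rank warning.

*Encoding test.* A variable is "encoded" when dropping all of its columns
(all trials, all lags) significantly reduces explained variance. The test
is the partial F-test on the extra sum of squares; because of the rank
deficiency, the numerator degrees of freedom are the *rank* gained by the
dropped columns and the residual degrees of freedom are n − rank(full),
not column counts — with column counts the statistic would be deflated
and the test conservative. With rank-based degrees of freedom the type-I
error is nominal: the acceptance suite measures the per-variable flag
rate on 1000 simulated AR(1) null neurons and requires it inside
[0.03, 0.07] at α = 0.05. A permutation alternative (circular shifts of
the trace, with the autoregressive column rebuilt per shift) is available
behind `method="permutation"`.

Per-trial encoding drops only that trial's L columns. No multiple-testing
correction is applied across neurons by default (nominal α per neuron);
Bonferroni across the four variables sits behind the `bonferroni` flag.

*Validity caveat.* The F reference distribution is exact for fixed
regressors; with a lagged dependent variable it is asymptotic. At the
default session length (~1700 bins) the measured null calibration is
nominal.

*Collinearity diagnostics.* VIF per column (1/(1−R²) of that column on
all others, infinite for exact duplicates), condition index
√(λmax/λmin) of the correlation-scaled cross-product matrix (correlation
scaling chosen because the alternative — raw cross-products — makes the
index depend on arbitrary column units; the choice is recorded in the
report), and a minimum-eigenvalue path over predictor groups added in
model order (AR, tone, shock, ITI, speed). Flags at VIF > 10 and
condition index > 30. Substituting a freezing indicator (the complement
of movement during the ITI) for speed reproduces the expected pathology:
freezing is near-collinear with the ITI dummies and its columns blow past
the VIF threshold, which is the rationale for preferring speed as the
continuous covariate.

## Population state

Activity is Z-scored per neuron against the session's first 5 minutes
(the pre-stimulus baseline); zero-baseline-variance neurons cannot be
standardized and are excluded with a logged ID. The baseline /
post-baseline dichotomy splits the session at the first shock onset, the
onset bin included in post-baseline.

The population-correlation matrix correlates the across-neuron population
vector at every pair of time bins. Epoch-wise means factor out the unit
diagonal; within-window means count each unordered bin pair once, and
cross-window means exclude any shared-bin diagonal entries. Bins with
across-neuron-constant vectors have undefined correlations and are set to
missing, excluded pairwise from means.

PCA operates on the time × neurons matrix with per-neuron mean centering
only (inputs are already baseline-Z-scored; no further rescaling). Signs
follow a deterministic convention: the largest-magnitude loading of each
component is positive. The Mahalanobis shift uses the pooled within-group
covariance of the baseline and post-baseline PC coordinates; the
formulation leaves the covariance unspecified, and pooling both groups is
the symmetric choice (a baseline-only covariance sits behind
`mode="baseline"` and is recorded in the result). Singular covariances
are ridge-regularized with a logged epsilon. The distance is invariant
under invertible linear maps of the coordinates when S is recomputed, a
property the acceptance suite verifies to 1e−8.

The state classifier reconciles two descriptions — "stratified 10-fold"
and a 75/25 train/test split — as 10 repeated stratified shuffled 75/25
splits with the mean of held-out accuracies (satisfying both the training
fraction and the 10-iteration mean); literal stratified 10-fold CV is
available behind `mode="kfold"`. Because the classes are imbalanced, the
majority-class proportion is always reported alongside accuracy as the
chance level.

Epoch quantification windows default to 28 s of the cue, 5 s from shock
onset, and a 5-s ITI window starting where the shock window ends. Whether
"5 s during and after the footshock" denotes one window or two is
ambiguous, so the shock window and a separate post-shock window label are
both computed. Two ITI boundary conventions are exposed
(`iti_convention`): the default starts the ITI at shock offset; the
alternative excludes the 50-s post-cue quantification window.

## Photometry

The drift-correction description ("the linear regression of the signal…
subsequently subtracted") is ambiguous between regressing the 405-nm
control on time and fitting it to the signal channel. The default is the
standard isosbestic practice — affine least-squares fit of control to
signal, subtract the fitted control — which removes any component common
to both channels (bleach, motion) up to the fit error; `detrend-time`
implements the literal alternative. Both are recorded in the correction
metadata. A constant control channel cannot be scaled and falls back to
offset-only subtraction with a warning.

Whole-session normalization Z-scores against the pre-stimulus baseline
window; the baseline sd is assumed as the scale (the source convention
does not state it; flagged here and in the docstring). Peri-event rows
are Z-scored against their own 20-s pre-onset segment; events whose
baseline or window leaves the recording are dropped and logged. AUCs are
signed trapezoidal areas in Z·s (responses can be negative), with the
named cue-locked windows (0–10, 10–28, 28–33, 33–50 s).

Transient detection is unspecified at the source, so it is defined here
as local maxima at or above a threshold (default 2.5 robust-Z via
median/MAD, robust to bleach residue) with peaks at least one refractory
interval apart (default 1 s; higher peaks win). Events are timestamped at
the peak. With this definition the count is provably monotone
non-increasing in the threshold.

## Behavior

Freezing is scored as speed below a threshold (default 0.5 cm/s, a
typical immobility criterion) sustained for at least `min_bout` (default
1 s); this is a surrogate for video-based scoring and is the only
freezing measure applied to synthetic traces. The spontaneous-alternation
percentage follows the literal printed formula — alternating triplets
divided by *total* entries × 100 — even though entries − 2 is the
field-standard maximum; the alternative sits behind
`mode="max-possible"`.

## Synthetic data

The generator emulates the study conditions: a 5-minute baseline followed
by 6 trials of 30-s tones co-terminating with 2-s shocks and 60-s ITIs
(conditioning); 10-s CS+/CS− cues with 0.5-s shocks, 60-s ITIs and a
2-minute habituation (cue discrimination, CS+ first, equal counts,
random interleaving). Neurons follow exactly the encoder's linear model
(weights × lagged indicators + lagged speed + AR(1) + Gaussian noise), so
parameter recovery is exactly well-posed; an optional single-exponential
calcium kernel (τ = 1 s, GCaMP7s-like) is off by default because the
analysis model is fitted directly to ΔF/F-style traces. Speed is a
clipped AR(1) process (mean 4 cm/s) with freezing bouts injected at
2%/s before and a configurable probability after the first shock.
Photometry adds a monoexponential bleaching drift (modeled as a decaying
loss starting at zero), a shared low-frequency motion artifact, and white
measurement noise (sd 0.02, small relative to evoked transients as in
demodulated recordings), with the control channel carrying a scaled copy
(0.8) of the common components and none of the true signal.

The post-shock state shift used as a ground-truth fixture adds a static
per-neuron offset (gain × random loading, displacing the post-shock
population vector) plus a shared non-negative latent factor |f_t| with
per-neuron loadings. The factor is rectified deliberately: a zero-mean
factor would raise the *magnitude* of pairwise population correlations
but not their mean, whereas a one-sided factor raises the mean
within-epoch PCC monotonically with its amplitude, which is the
population-coherence phenotype the fixture must emulate.

What the generator does **not** emulate: spike-to-fluorescence
nonlinearity, neuropil contamination and extraction cross-talk,
non-Gaussian and non-stationary noise, slow representational drift, or
video-based freezing. Passing tests therefore demonstrate correctness of
the analyses under the stated generative model, not robustness to every
artifact of real recordings.

## Problem sizes and determinism

The test and acceptance runs use the default 6-trial session (≈1700 bins
at 2 Hz): 1000 null neurons for type-I calibration, 100 neurons (20
tuned) for recovery, 50-neuron populations and 20 seed pairs for the
state-shift ordering, sizes at which the shared-design fitter (one SVD
basis per nested model, then per-neuron projections) completes the full
battery in seconds. Every stochastic step draws from
`numpy.random.default_rng` seeded explicitly; pipeline stages derive
independent sub-seeds from the master seed via `SeedSequence`, so
identical configurations give byte-identical reports and individual
stages can be rerun in isolation.

## Known limitations

- The encoder is strictly linear-Gaussian OLS; no regularized or
  generalized variants, and no hierarchical pooling across animals.
- State-space analyses use two principal components only, matching the
  downstream distance and classifier definitions.
- The F-test's validity with the autoregressive regressor is asymptotic;
  very short sessions (a few hundred bins) may show miscalibration.
- Photometry processing starts from demodulated two-channel traces;
  lock-in demodulation and vendor file formats are out of scope.
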