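# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `eegfuse`, in the order the pipeline runs.

## Synthetic motor-imagery model

The generator emulates the sensorimotor-rhythm physics the pipeline
targets, not a full head model. Each trial of each channel is

    x(t) = n(t) + A · g · sin(2π f_mu t + φ),

where `n(t)` is unit-variance 1/f^α noise (spectrally shaped white noise,
α = `noise_exponent`, default 1), `f_mu` = 10 Hz, `φ` is a uniform random
phase per trial and channel, `A = snr` is the mu amplitude in units of the
noise standard deviation, and the gain `g` is `erd_ratio` at the electrode
contralateral to the imagined hand (C3 for right-hand trials, C4 for
left-hand) and 1 elsewhere. Defaults: `erd_ratio = 0.4`, `snr = 2`,
`fs = 250 Hz`, 4-second epochs — the attenuation and amplitude levels are
the conditions used throughout the test battery, and the sampling-rate
default matches the common 250 Hz MI recording setup (128 and 500 Hz are
the other rates the loaders anticipate). Trials alternate left/right and
each trial draws from a `SeedSequence` substream keyed by (seed, trial
index), so growing the trial count never reshuffles earlier trials and
identical configs are bit-identical.

What the generator deliberately omits: ocular/muscular artifacts,
inter-trial nonstationarity, volume-conduction mixing between channels,
beta-band ERD and rebound, and subject variability. Passing tests
therefore demonstrate the pipeline's correctness and its sensitivity to a
planted contralateral mu effect; they do not predict accuracy on real
recordings, where these nuisances dominate. On the clean synthetic task
the cross-validated accuracies saturate near 1.0 at the default effect
size; the chance-level control (no planted effect) is the guard against
optimistic bias.

## Preprocessing

The band-pass is a Butterworth design (`scipy.signal.butter`, second-order
sections) with −3 dB points at the design edges, applied forward–backward
(`sosfiltfilt`, reflect padding). Zero-phase filtering was chosen because
the analysis is offline and group-delay distortion would leak into the CSP
covariances; it squares the magnitude response, and "order 4" refers to
the design order handed to the band-pass designer. Epochs are filtered
directly (with padding) rather than filtering a continuous recording
before epoching; for the 4 s epochs used here the settling error is below
the 1e-8 impulse-response floor the tests enforce. Channel matching is
case-insensitive ("CZ" ≡ "Cz") because 10–20 electrode names are spelled
inconsistently across datasets.

## Feature extraction

**AR.** The reported features are the coefficients of
`y(t) = −Σ aᵢ y(t−i) + e(t)`; estimators return the regression form
`y(t) = Σ ρᵢ y(t−i) + e(t)`, so the features are `−ρ`. Order 6 with the
Burg estimator is the default: Burg is stable on short epochs, and order 6
is standard for the 8–30 Hz band while keeping the fused dimension (24)
above the selection target (20). Yule–Walker and ordinary least squares
are available for cross-checks.

**CSP.** Per-trial covariances are trace-normalized (`XXᵀ/tr(XXᵀ)`) and
averaged arithmetically within class. The whitener of the class-sum
covariance is `P = λ^{−1/2}Uᵀ` — the exponent −1/2 is the only choice for
which `P R_m Pᵀ = I` and the paired eigenvalues satisfy `λ₁ + λ₂ = I`,
which the tests assert to 1e-8. With three channels all three filters are
used (no pair truncation). Filter rows are sign-normalized (largest
weight positive) for determinism. The feature is the raw variance of each
filtered component; a log-of-normalized-variance variant sits behind a
flag with a 1e-12 floor. A rank-deficient `R_m` (e.g. duplicated
channels) raises with a regularization hint rather than silently
pseudo-inverting.

**DWT.** `pywt.wavedec` with db4, 3 levels, symmetric boundary by
default; the feature is the mean squared coefficient at the configured
level (level-3 detail by default). Level-3 detail spans one octave
`[fs/16, fs/8]` — 8–16 Hz at `fs = 128`, which is why the study-scale
evaluations in the test battery and the acceptance script run at 128 Hz:
there the feature reads out exactly the mu band the ERD modulates. The
detail/approximation choice at the feature level is configurable since
"layer 3" alone does not pin it down; detail is the default because the
level-3 approximation spans 0–8 Hz, below the band of interest. Energy
conservation of the orthogonal transform holds exactly only under
periodization boundaries, so that property is checked in that mode while
symmetric padding (fewer boundary artifacts per subband) remains the
feature default.

**Fusion.** Plain column concatenation with per-column provenance
records; z-scoring is fitted on training rows only and applied to all
rows, with unit scale substituted for constant columns. De-fusing by
provenance recovers the parts exactly (pre-standardization), which the
tests use as a losslessness check.

## Feature selection

**Extremely randomized trees.** Trees are grown on the full training
sample (no bootstrap). At each node the candidate features are `m` drawn
without replacement (`m = M`, all features, by default); one cut-point per
candidate is drawn uniformly between the feature's min and max over the
node; the winning cut maximizes the normalized information gain
`2·I/(H_split + H_class)` (entropies in bits, `0·log 0 = 0`; the base
cancels in the ratio). Splitting stops at pure nodes or fewer than
`n_min = 2` samples. Importance of a feature is the sum over its winning
nodes of `score × node-sample-fraction`, averaged over the `R = 10` trees
and normalized to sum to one — the standard impurity-weighted scheme with
the normalized gain as impurity. The kept set is the top 20 by
importance, matching the cardinality the other selectors are pinned to so
comparisons are like-for-like; ties break toward the lower column index,
and seeds expand to per-tree substreams for determinism.

**RFE.** Base estimator is a linear support-vector regressor
(`sklearn.svm.SVR(kernel="linear")`, labels coded ±1); ranking criterion
is the squared weight; exactly one feature is dropped per round (ties:
lowest column index) until 20 remain. Asking to keep more features than
exist keeps all with a warning rather than raising.

**PCA.** Centered, not re-scaled (fusion already standardizes);
components capped at `min(n_trials − 1, n_features)` with a warning when
the request exceeds the feasible rank.

**ReliefF.** All training rows sampled; `k = 10` neighbors;
Manhattan distance on standardized features; feature differences
normalized by the feature range; neighbor ties broken by row index so
duplicate rows behave deterministically.

Selectors expose `apply_selection(model, X)` which takes no labels — the
interface itself prevents held-out label leakage, and a metamorphic test
(permuting held-out labels) verifies that no fitted quantity changes.

## Classification and evaluation

Linear-kernel SVM (`SVC(kernel="linear")`). The penalty grid is
10⁻³…10³ in decade steps; the winner maximizes mean stratified-CV
accuracy with ties to the smallest C (simplest model). Stratified folds
are used because per-class counts are small. The libsvm solver's
iteration count is capped at 10⁵: on non-separable data with large C it
otherwise spends millions of iterations converging to a solution that
loses the grid search anyway; capped fits are deterministic and the cap
is far above what any informative configuration needs.

`cross_validate_pipeline` fits everything label-dependent — CSP filters,
fusion standardization, the selector, and the inner C search — on the
training rows of each outer fold only. AR and DWT features are computed
once for all trials since they are label-free and trial-local. The inner
grid-search CV uses up to 10 folds, reduced to the training split's
smallest class count when necessary. The comparison grid reuses identical
outer folds across selectors, so per-fold accuracies are paired and the
paired t-test applies; a zero-variance difference vector reports
`(t = nan, p = 1.0)` by convention instead of raising. Accuracy is the
plain fraction correct.

## Problem sizes

The test battery and the acceptance script evaluate the study conditions
at 100 trials per class, 4 s epochs at 128 Hz, 10-fold CV, with 5 seeds
for the fused-versus-single comparison and 20 seeds for the ET
planted-feature rank check; spectral and moment oracles use up to 200
trials per class, and AR recovery uses series of length 10⁴–5·10⁴. These
sizes give sampling error comfortably below every asserted margin.

## Known limitations

- Two classes only; multi-class CSP/selection extensions are out of scope.
- The ET selector's importance scheme is one standard choice among
  several; rankings (not the split score itself) could differ from other
  aggregation conventions on near-tied features.
- The EDF/GDF adapter depends on annotation conventions of the source
  files; epoching windows and event codes must be supplied by the caller.
- On the clean synthetic task most configurations saturate near perfect
  accuracy, so selector differences are visible mainly through degenerate
  (tied) comparisons; real, noisier data is where the selectors separate.
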