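# Methods

This note documents the models, numerical choices and open design
decisions behind the package, and what the synthetic data can and cannot
establish about real helpline recordings.

## Signal processing

Calls are mono 8 kHz (telephone band, ~300–3400 Hz). Preprocessing
quantizes to the 16-bit PCM grid, removes the DC mean, and applies
first-order pre-emphasis with α = 0.97 (the standard speech value; the
coefficient is exposed in `ExtractionConfig`). Analysis frames are 40 ms
(320 samples) with 50 % overlap and a Blackman window; trailing partial
frames are discarded and frame times are frame centers. A frame is
*silent* when its pre-window RMS falls below −50 dBFS; silent frames are
excluded from every downstream table. Both thresholds are configuration,
not science: the corpus this emulates reported only that about half of all
material was removed as silence.

Spectra use a 512-point FFT (15.6 Hz bins), one-sided, Parseval-scaled so
band powers sum to frame energy. Feature definitions worth noting:

- **Formants** come from Burg LPC of order 10 (2 + rate/1000). Roots with
  positive imaginary part give f = θ·rate/2π and bandwidth
  b = −(rate/π)·ln|r|; candidates must lie in (90, rate/2 − 50) Hz with
  bandwidth < 400 Hz (wider poles model tilt or noise), and successive
  formants must be ≥ 200 Hz apart (a single strong tone otherwise yields
  three stacked poles). The estimator expects pre-emphasized input; on
  synthetic three-resonator vowels (500/1500/2500 Hz) mean recovery is
  within ±50 Hz.
- **Harmonicity.** The fundamental itself lies below the telephone
  passband, but periodicity survives in the waveform: the peak normalized
  autocorrelation r\* over lags for 75–300 Hz gives
  NHR = (1 − r\*)/r\*, clipped to [0, 10]. **Subharmonic depth** measures
  period doubling (rough phonation) as the dB excess of the
  autocorrelation at lag 2T\* over lag T\*. A 40-ms Blackman frame has a
  ~150 Hz mainlobe and cannot *spectrally* resolve components at f0/2
  offsets, so the period-2 component is read in the time domain; the
  measure is zero for a clean pulse train and grows monotonically with
  alternate-period amplitude alternation.
- **Loudness** pools power into 1-bark critical bands (Traunmüller scale)
  and sums band intensity^0.3 (Stevens' law); it is exactly homogeneous of
  degree 0.3 in power, and together with RMS it is the only gain-dependent
  feature — all spectral-shape features are gain- and polarity-invariant.
- **Sequence context** (flux, novelty, roughness) uses a 5-frame (100 ms)
  window that never crosses a segment boundary; novelty uses a Foote
  checkerboard kernel with the center row/column excluded so constant
  similarity scores exactly zero; roughness is the fraction of
  amplitude-envelope modulation energy in 30–150 Hz.

## Correlation screening

Greedy pruning at |r| ≥ 0.9: repeatedly find the worst correlated pair and
drop the member with the larger mean absolute correlation to all other
features (the caret convention), with an alphabetical tie-break. The
threshold and rule are package choices — the original study reported only
that 24 features became 19.

## The selection model

A binomial two-level additive model with logit link: intercept, a sex main
effect, per-(feature, sex) centered cubic P-spline smooths (9 basis
functions, uniform knots) and caller-indicator random intercepts.
Penalties: a second-difference coefficient penalty per smooth (uniform
knots make its null space exactly the linear functions), a null-space
"shrinkage" penalty that lets whole terms be selected out, and a ridge on
the caller block whose weight plays 1/σ²_caller. Fitting is penalized IRLS
(relative deviance change < 1e-8, 200 iterations max). The three penalty
weights (shared curvature λ, shrinkage λ0, caller ridge λc) are chosen by
GCV with γ = 1.4 on the converged working model, scanned over log-spaced
grids inside a performance iteration (two rounds). A shared λ across
smooths — rather than per-term — keeps the grid search tractable; the
shrinkage penalty still lets individual terms flatten.

**Inference under dependence.** Frames within a segment share their label
and carry AR(1) feature noise; callers contribute voice-identity offsets
that are confounded with their distress propensity. Model-based
(frame-iid) Wald tests are therefore badly anti-conservative (measured
null sizes of 0.2–0.4 at α = 0.05 on study-structured synthetic data).
The package handles the two levels separately:

- *caller level*: the caller-intercept block, left nearly unpenalized by
  GCV, absorbs caller-level confounding structurally;
- *segment level*: term tests use a segment-clustered sandwich covariance
  whose score contributions are built from leave-one-segment-out working
  residuals (a CR3-style (I − H_gg)⁻¹ adjustment — in-sample residuals of
  a high-edf penalized fit are deflated and would shrink the sandwich).
  The Wald statistic b′V⁻⁽ʳ⁾b with rank r = ⌈edf⌉ is referred to
  F(r, G − 1) with G the number of segments.

On independent-label null data this test attains size ≈ 0.05 with
near-uniform p-values; on the study-structured generator the planted
effects are recovered with ~100 % recall and a median of zero false
positive features. Reported per-term quantities: the least-squares linear
component of the fitted smooth against the z-scored feature (β, with
delta-method robust SE and ±1.96·SE CI), edf (trace of the per-block
influence matrix), the approximate F, and p. Deviance explained is the
adjusted analogue 1 − (D/(n−edf))/(D₀/(n−1)); on data whose labels are
constant within segments it includes genuinely fitted segment- and
caller-level structure, so it is near zero only under a frame-iid null.

The denominator df of the original study's F-tests (a fixed 1455) is
unexplained there; this package derives its reference distribution from
the clustering structure instead.

## Clustering and principal components

k-means (25 k-means++ restarts, seeded, labels renumbered by descending
size) on z-scored features; the scree's elbow is made explicit: the chosen
k is the smallest whose marginal explained-variance gain falls below 25 %
of the first gain. The 2-cluster solution is validated by logistic
regression of membership on the features (McFadden pseudo-R²) and by
Cramer's V against caller sex.

Clusters and their two principal components are computed on the **full
screened feature set**, not the selected subset. This resolves an
ambiguity deliberately: PCs of the selected features alone are a rotation
of axes the boosting's per-feature splines already span and cannot add
classification signal, whereas PCs of the wider space summarize the joint
phonation shift — the only reading under which cluster variables can
improve a classifier that already sees the selected features, as observed
in the study this emulates. PC signs are fixed so each component
correlates positively with its highest-loading feature.

## Component-wise gradient boosting

Functional gradient descent on binomial deviance with ν = 0.1. Base
learners: a P-spline per selected feature, a sex-difference P-spline per
feature (moderation selectable per component), one ridge block of caller
intercepts, and a P-spline per cluster PC — every learner's penalty is
tuned by bisection so its effective df is 4.0 ± 0.1, keeping selection
fair across learner types (a df-1 linear learner essentially never wins
against df-4 splines, which is why the PC learners are splines too). Each
iteration fits all learners to the negative gradient (y − p) by
pre-factorized penalized least squares and takes a ν-step of the best by
residual sum of squares; training risk is non-increasing by construction
and halving ν while doubling mstop changes final training risk by < 1 %.

Validation is grouped throughout: mstop minimizes mean out-of-fold
deviance over caller-grouped, prevalence-balanced 10-fold CV; the headline
metric is leave-one-caller-out CV, where the held-out caller's
random-effect contribution is structurally zero. **All folds share the
pooled base-rate offset**: a per-fold offset (training prevalence)
anti-correlates with the held-out caller's prevalence and injects spurious
negative discrimination — with the shared offset, a caller-confounded null
(labels constant per caller, features pure noise) yields LOCO AUROC 0.500
while the in-sample AUROC exceeds 0.9, which is exactly the leakage
signature the grouped design exists to expose.

AUROC is the midrank statistic, AUPRC the stepwise precision–recall
integral (both cross-checked against independent implementations in the
test suite); CIs are percentile bootstrap resampling whole callers. The
operating threshold maximizes Youden's J over observed cutpoints, ties
broken toward 0.5. Variable importance credits each learner with its
summed in-sample risk reduction, normalized to 1.

## Segment aggregation

A segment's score is the mean out-of-fold probability of its scored
frames; predicted high iff mean ≥ τ (the frame-level Youden threshold —
no separate segment threshold is fitted). Percentages are rounded half-up,
2 dp at frame level and 1 dp at segment level, and always recompute
exactly from the reported counts.

## The synthetic generator

Defaults mirror the emulated corpus: 120 callers (87 female / 33 male),
negative-binomial segments per call (mean 7.7, SD 4.22), ~100 frames per
segment (≈ 117k frames), beta-binomial(10) distress ratings with marginal
mean 4.92 and SD ≈ 2.1, dichotomized at 4. Caller structure: a N(0, 1)
logit intercept shifts each caller's rating propensity, and N(0, 0.4)
per-feature voice offsets make features caller-identifiable —
deliberately creating the caller-level confounding the inference must
survive. Within segments, feature noise is AR(1) with ρ = 0.6 (unit
stationary variance). A latent two-mode phonation state, persistent
within a segment and partially distress-driven, shifts six features
jointly, giving the frame cloud its cluster structure. Distress effects
enter as monotone (or mildly curved) shifts in the directions of the
significant sex-moderated terms of the emulated study — male: louder,
lower F1, shallower subharmonics; female: higher entropy,
noise-to-harmonics, median frequency and spectral slope, shallower
subharmonics — with magnitudes calibrated once so that the default
configuration yields leave-one-caller-out AUROC ≈ 0.93 (high but
imperfect, so segment aggregation has visible work to do).

The audio generator synthesizes the same structure: jittered glottal
pulse trains (f0 110–135 Hz male, 185–225 Hz female) with one-pole
glottal roll-off, alternate-period amplitude alternation that *decreases*
with distress, three formant resonators with mild caller-specific
vocal-tract scaling, aspiration noise, distress-dependent gain/F1/tilt
shifts, interleaved silence, and a 300–3400 Hz band-pass at 8 kHz. Because
raters in such studies deliberately annotate a diversity of distress
within each call, the generator enforces that both label classes appear
in every multi-segment call. The audio aims at testable acoustic
structure, not perceptual realism: no articulation, no linguistic content,
no channel noise beyond aspiration.

**What passing tests show — and don't.** Recovery, calibration and
leakage results on this generator demonstrate that the pipeline's
machinery is correct under the stated dependence structure. They do not
show that real distressed speech carries these effect sizes, that the 21
features are optimal for real telephone audio, or that a particular
AUROC is attainable on confidential recordings.

## Problem sizes

Tests and the acceptance script run scaled-down configurations chosen to
preserve the corpus's proportions (segments ≫ model parameters): model
recovery uses 30 callers × ~8 segments × ~40 frames (~8–9k rows,
25 replicates); boosting discrimination 40 callers (~17k rows); the audio
pipeline 6 callers / 18 segments / ~22 s of audio. At many fewer segments
the selection model approaches in-sample separation (the weights saturate
and Wald-type quantities degrade), which is a property of the scale, not
of the estimator.

## Known limitations

- Residual within-segment autocorrelation is not modeled inside the GAMM
  likelihood; it is carried by the generator and handled at inference time
  by the clustered sandwich. A GEE- or AR(1)-working-correlation fit is a
  natural extension.
- Smoothing parameters are shared across smooths (per-term selection would
  need a Fellner–Schall or full mgcv-style optimizer).
- The subharmonic measure is autocorrelation-based by necessity at 40 ms;
  it saturates for alternation depths near 1.
- The elbow rule can return k > 2 on gradient-structured data (flagged);
  cluster validation is always reported for the 2-cluster solution.
- Exact numeric parity with any third-party feature extractor is a
  non-goal; features follow the standard definitions stated here.
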