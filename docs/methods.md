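# Methods

This note documents the models and estimators implemented in `gaitrisk`,
the choices made where several constructions are defensible, what the
synthetic generators do and do not emulate, and the package's known
limitations. Units are SI throughout (acceleration m/s², frequency Hz,
durations s) unless stated otherwise.

## 1. The analysis chain

The package implements the full chain used in daily-life fall-risk studies
built on trunk accelerometry: 10-second walking epochs → 30 per-epoch gait
characteristics → per-participant week summaries (10th/50th/90th
percentiles) → univariate association scans → three nested stepwise
logistic fall-prediction models → a Monte Carlo block-permutation test for
the significance of AUC improvements. The scientific question it
operationalizes is whether a person's *extreme* gait quality over a week
(the percentile tails) predicts falling better than their *typical* gait
(the median).

## 2. Per-epoch gait characteristics

All estimators operate on one tri-axial epoch of dynamic (gravity-removed)
acceleration, mean-centred per axis; there is no tilt correction (synthetic
signals are axis-aligned; alignment of real data is an extension point).
Undefined values propagate as missing with a reason code, never as
sentinels, so percentile summarization skips rather than absorbs them.

**Spectra.** Welch estimates with 5-s Hann windows, 50% overlap and
constant detrend — a stable compromise at 10-s epochs. Harmonic amplitudes
are recovered by integrating spectral *energy* over a small bin
neighbourhood (±1 bin for harmonic combs, ±3 bins for the dominant peak)
and converting to amplitude with the window's energy gain; unlike reading
the peak bin, this is insensitive to scalloping (≤ ~1% amplitude error for
an off-bin sinusoid). The low-frequency-percentage feature alone uses a
full-epoch Hann periodogram, because the sub-Hz band needs the finest
resolution the epoch affords and a power *fraction* does not benefit from
Welch averaging.

**Stride frequency.** VT and AP are fundamental at the *step* frequency
(2·f_stride); ML at the stride frequency. The dominant Welch peak of VT is
located in the step band (0.8–3.2 Hz by default) and halved. Two guards
apply: (i) the peak must exceed 4× the median spectral power, and the
unbiased autocorrelation near one stride lag must exceed 0.2, otherwise
the epoch is flagged feature-undefined (white noise and non-gait segments
fail here and are dropped downstream); (ii) in markedly asymmetric gait
the stride fundamental itself can dominate the VT spectrum — the two
readings are disambiguated by the autocorrelation at the would-be step
lag, which is positive for a genuine step periodicity and non-positive
when the peak is the whole-stride fundamental. The disambiguation assumes
stride frequencies ≳ 0.75 Hz; very slow gait (< 0.6 Hz stride) with strong
asymmetry could still be misread, a documented limitation.

**Stride regularity** is the unbiased normalized autocorrelation at the lag
nearest one stride, peak-refined within ±10% of that lag. **Harmonic
ratio** sums amplitudes of the first 20 stride harmonics: even/odd for
VT/AP, odd/even for ML; a vanishing denominator (or a ratio beyond it) is
capped at 20 with a flag. **Index of harmonicity** is the power at the
axis fundamental divided by the power summed over it and its first five
harmonics. **Frequency variability** is the coefficient of variation of
the dominant in-band frequency across 2.5-s sub-windows with 50% overlap
(zero-padded periodogram, parabolic peak refinement; ≥ 3 sub-windows
required).

**Sample entropy** uses template length m = 5 and tolerance r = 0.3
interpreted as a fraction of the per-epoch, per-axis SD (the field's
standard convention when no unit is given), Chebyshev distance, ≤ r
matching, self-matches excluded, with both template lengths counted over
the first N−m templates so the ratio is well-defined. A constant signal
yields 0; zero matches yield missing, not infinity. The implementation
AND-combines a pointwise match matrix along diagonal shifts; it is verified
exactly (integer counts) against an independent per-template brute-force
counter in the tests.

**Local dynamic stability** is a Rosenstein-style short-term logarithmic
divergence rate: delay embedding with dimension 5 and delay 10 samples,
nearest neighbour under a one-stride temporal exclusion, least-squares
slope of the mean log-divergence curve over 0–0.5 stride time, in 1/s.
Higher values mean faster divergence, i.e. less stable gait. Note that the
estimator responds to *any* divergence source: on a noiseless signal with
stride-frequency wander it reports the (large) divergence due to phase
diffusion from a near-zero initial separation. Degradation studies that
want additive noise as the only factor must therefore fix the wander to
zero, as the test suite does.

**Gait speed** follows the inverted-pendulum model: VT acceleration is
doubly integrated to vertical displacement in the frequency domain
(spectral division by −ω², content below 0.4 Hz zeroed to suppress drift —
chosen over time-domain filtering because Butterworth transients at such
low cutoffs contaminate most of a 10-s epoch), the per-step vertical
excursion h gives step length 2√(2ℓh − h²) with configurable leg length
ℓ (default 0.9 m), speed is mean step length × step frequency and speed
variability the SD of per-step speeds; edge steps are discarded. On
synthetic epochs with known excursion the estimator is accurate to ~1%.

## 3. Week summaries

Epochs suspected to reflect running are discarded: stride time < 0.8 s
*or* VT RMS > 5 m/s², both strict inequalities (boundary values are
walking). Rows with undefined stride time are also dropped — they cannot
be confirmed as walking. Percentiles (10/50/90 by default) use the linear
interpolation rule between order statistics; a participant-characteristic
summary requires at least 10 defined epoch values (configurable), else it
is reported missing. Between-weeks reliability uses ICC(2,1) — two-way
random effects, absolute agreement, single measure — computed from the
ANOVA variance decomposition and cross-checked against an independent
implementation in the tests.

## 4. Risk models

Predictors are z-transformed (coefficients are log-odds per SD;
zero-variance columns are flagged and excluded). Logistic models are fitted
by Newton maximum likelihood with step halving (tolerance 1e-8); perfect
separation is detected and raised, never silently returned. The stepwise
rule adds, at each step, the candidate whose *added-coefficient Wald p* is
lowest and below α = .05, provided its absolute Spearman correlation with
every already-selected parameter (computed on untransformed columns) is at
most .7; ties break lexicographically by parameter name, so model building
is deterministic. A likelihood-ratio entry criterion would be the natural
alternative; the Wald form was chosen because it is what a single
coefficient's reported p-value tests, and both agree to first order at
these sample sizes. Both entry-step and final-refit p-values are reported.
Candidate sets: Model 1 = {fall history, GDS}; Model 2 adds the 7 activity
amounts and all characteristic medians; Model 3 replaces a median by its
10th/90th percentile when that percentile's univariate p is lowest and
below .05 (else the median is kept; incomplete percentile triplets default
to the median). Missing summaries are handled by complete-case fitting per
model, with counts logged. AUC is in-sample (no cross-validation), computed
by the rank statistic with ties counted ½; calibration is the
Hosmer–Lemeshow chi-square over deciles of predicted risk with g−2 degrees
of freedom, merging degenerate groups.

## 5. Block-permutation model comparison

Under the null that the sensor block (all activity amounts and all
characteristic percentiles) carries no information about falling beyond
the questionnaire, the block may be permuted as a unit across participants
without changing the joint distribution. For each of 1000 permutations one
uniform random permutation (fixed points allowed — they are rare and
harmless) reassigns the entire block; both models are rebuilt from scratch
on the permuted table, *including* re-running the percentile-replacement
rule when Model 3 is involved (the construction is part of the procedure
being tested, so it must be repeated inside the resampling loop). The
p-value is the strict-count ratio #(permuted ΔAUC > observed ΔAUC)/N; the
(k+1)/(N+1) estimator is also reported. Per-permutation seeds derive
deterministically from the master seed, so results are independent of
execution order. The questionnaire-only model is invariant under the
permutation and is cached. As a diagnostic for the known conservatism of
this comparison (permuted baseline models typically start from a lower
AUC), the distribution of permuted AUCs of both models is reported
alongside p.

Calibration, measured in the test suite on 100 null cohorts × 199
permutations (n = 100), gives a 7% rejection rate at α = .05. The null
p-value distribution is uniform over the decision range but *not*
globally: because both models may select nothing beyond the questionnaire,
permuted ΔAUC has an atom at 0 and the strict-count p is bounded away
from 1 (empirically ≲ 0.78). This is a structural property of the
strict-count estimator for nested in-sample models, so the suite checks
empirical-CDF closeness to uniform at α ∈ {.05, .1, .2, .3} rather than a
global uniformity statistic.

Internally the permutation loop runs on a precomputed engine: per-column
z-scores and ranks are reindexed (a row permutation changes neither), the
Spearman screen reduces to one small correlation matrix per permutation,
and all "add one candidate" fits of a stepwise round are solved by one
batched Newton iteration. This is what makes 1000 full stepwise rebuilds
per comparison run in well under a minute.

## 6. Synthetic data

**Signal level.** An epoch is a sum of four even and four odd stride
harmonics per axis with fixed per-harmonic phase offsets, phase-continuous
frequency wander (an Ornstein–Uhlenbeck walk of the instantaneous stride
frequency, relaxation 1 s, stationary SD = `freq_jitter_sd`) and additive
white noise. The asymmetry parameter scales the odd harmonics on VT/AP and
the even harmonics on ML, so raising it degrades exactly the step symmetry
the harmonic ratio measures; with all stochastic terms zero the signal is
exactly periodic. The first even VT amplitude is tied to a vertical
excursion h through a = (h/2)(2π·2f)², closing the loop for the
inverted-pendulum speed estimator. Default amplitudes give VT RMS
≈ 1.3 m/s² and gait speed ≈ 0.8 m/s — plausible for older adults and
safely inside the ±6 g device range. A cohort draws one latent gait-quality
scalar per participant, maps it to degradation parameters (more noise,
wander and asymmetry, lower stride frequency and excursion as quality
falls), adds questionnaire data (fall history, GDS) and seven activity
amounts from truncated normals with plausible means, and draws the fall
outcome from a logistic model on the z-scaled generative parameters, whose
coefficients are returned as ground truth.

**Feature level.** Model-level studies need hundreds of participants ×
thousands of permutations, for which raw-signal synthesis plus feature
extraction is needlessly expensive. The feature-level generator draws
epoch-level values of the 30 characteristics directly, on a standardized
scale: participant mean = (quality loading, signed by the field's
conventions: entropy/instability/variability load negatively) × latent
quality + participant noise; epoch values scatter around it with a
*participant-specific* SD, log-linear in a second latent (dispersion
τ = 0.35). The heteroscedastic dispersion is what gives the 10th/90th
percentiles information beyond the median — exactly the situational
variability percentile extremes are meant to capture — and is what makes
the "extreme-driven outcome" studies meaningful. Percentile summaries are
computed from the simulated epoch values by the same summarization code
used for real features, and the outcome is drawn from a logistic model on
the z-scaled *realized* summary columns, making coefficient recovery
exact in expectation. The joint distribution of characteristics in real
cohorts is unknown; a single shared quality factor plus independent noise
is a deliberate simplification that produces realistic cross-feature
correlations (~0.3–0.4) without asserting more structure than is known.

**What passing tests do and do not show.** The synthetic cohorts have
Gaussian features, a single latent factor, no missing data beyond what the
filter creates, no device artefacts, no turning or non-walking
contamination, and exchangeability of the sensor block holds *exactly*
under the null construction. Green tests therefore validate the
estimators, the selection machinery and the resampling logic — not the
clinical performance of the models on real cohorts, which the in-sample
AUC would overstate in any case.

## 7. Numerical and degenerate-input conventions

Constant signals: RMS 0, sample entropy 0 at the function level, all other
characteristics flagged undefined for that axis (tolerance radii and
spectra are degenerate). Epochs failing the stride-frequency guards keep
only RMS, sample entropy and low-frequency percentage. Harmonic-ratio caps
are flagged. Perfect separation or singular designs in any stepwise
candidate evaluation mark that candidate inadmissible rather than aborting
the model. Hosmer–Lemeshow groups with degenerate expected counts are
merged with adjusted degrees of freedom. All stochastic code takes
explicit seeds; identical seeds give bit-identical outputs.

## 8. Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run at sizes chosen to exercise
every code path at study-like scale while remaining comfortable on a single
CPU: cohorts of 202 participants × 50 epochs for model studies, 1000
permutations for the shipped comparisons (199 inside the 100-cohort
calibration study), 50 seeds for recovery and designed-advantage studies,
and a 20-participant × 12-epoch raw-signal cohort for end-to-end
extraction fidelity.
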