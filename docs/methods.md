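# Methods

`phonotrf` implements a forward-encoding ("deconvolution") analysis of
phonological-feature processing in infant EEG recorded during continuous
speech, together with a synthetic-data generator that provides ground truth
for every stage. This note documents the models, the numerical choices, and
what the synthetic conditions do and do not show about real data.

## Predictors

Speech is annotated at the phoneme level (forced-alignment output read from
Praat TextGrids or TSV). Each phoneme maps to a bundle of 17 binary
Chomsky–Halle phonological features (canonical order: voiced, continuant,
sonorant, low, tense, back, strident, consonantal, long, syllabic, round,
high, coronal, anterior, nasal, labial, lateral). A feature's
*feature-continuous stretch* is a maximal run of adjacent phonemes (boundary
gap < 1 ms, a float-noise guard for forced-alignment output) that carry the
feature; a silence following a stretch is appended to its duration, up to
the next phoneme onset and never past the end of the file, because no new
phonological information arrives during the pause. A silence ends the
stretch — the next feature-positive phoneme starts a new one. Diphthongs
are single labels with their own bundles; the shipped German SAMPA table is
a versioned CSV that users can replace.

Predictors are sampled at a common analysis rate, default 100 Hz —
comfortably above twice the 10 Hz edge of the EEG analysis band while
keeping lagged design matrices small:

* **feature step functions** — 17 binary columns, 1 while the feature is
  active;
* **spectrogram** — 16 band envelopes, centres geometrically spaced on
  250–8000 Hz with edges at geometric midpoints, pooled from short-time
  Fourier magnitudes (25 ms windows); optional log(1+x) compression,
  default off;
* **pitch (F0)** — Praat-style autocorrelation per 40 ms frame, search
  range 75–600 Hz, parabolic peak refinement, voicing decided by a
  normalized-autocorrelation threshold (0.45) plus a relative-energy floor;
  unvoiced frames are 0.

## EEG preprocessing

Automatic cleaning for 500 Hz infant EEG on a 28-channel 10/10 montage
(TP9/TP10 are the mastoid sites):

1. zero-phase FIR filters with stated orders at 500 Hz — high-pass order
   1650 (−6 dB at 0.5 Hz) and low-pass order 332 (−6 dB at 47.5 Hz); orders
   scale proportionally at other rates. Filtering is single-pass noncausal
   (symmetric taps, 'same' convolution), so the stated orders and −6 dB
   points apply literally.
2. bad channels are the union of three rules: flat longer than 30
   consecutive seconds; rescaled-range (R/S) Hurst exponent below 0.7
   (dyadic window sizes, slope of log mean R/S versus log window); and
   average 1–100 Hz log power more than 2.75 SD from the cross-channel
   mean. The power rule is computed before the low-pass, which is why its
   band may exceed 45 Hz. A z-score across channels can flag an outlier
   only if enough channels are present (the max |z| of one outlier among n
   channels is (n−1)/√n), so the screen requires ≥ 4 channels and works
   best on full montages.
3. level-13 wavelet thresholding (coif4, periodized) removes large
   artifacts: detail coefficients are **clipped** at the per-level universal
   threshold σ√(2 ln n), σ from the median absolute deviation. Clipping
   removes the super-threshold excess (the artifact) while sub-threshold
   background EEG passes unchanged; the approximation level is untouched.
   Soft/hard alternatives were considered; clipping is the variant that
   both preserves a clean oscillation (its coefficients sit below the
   level's own threshold) and suppresses a spike by an order of magnitude.
4. spherical-spline interpolation of bad channels (MNE backend, standard
   10/10 positions); refused when more than half the montage is bad.
5. re-referencing to linked mastoids.
6. TRF preparation: 1–10 Hz zero-phase FIR (≤ 0.5 Hz transition), 1 s
   epochs, rejection of epochs whose **unfiltered** (pre-band-pass,
   post-cleaning) amplitude exceeds ±200 μV, and recombination with 1 s of
   zeros at discontinuities. Whether the amplitude check should use the
   fully raw or the cleaned signal is ambiguous; we use the cleaned,
   pre-band-pass signal. Participants/conditions retaining < 350 s raise an
   exclusion signal. The inserted zeros are deterministic non-data: they
   stay in the training rows (as in the recombined stream) but are excluded
   from accuracy scoring.

## TRF estimation

The TRF is a kernel w(lag, predictor, electrode) over lags −150…400 ms
(56 lags at 100 Hz). Estimation is ridge regression on the lag-expanded
design matrix (lag-major column order): w = argmin ‖Y − Xw‖² + λ‖w‖², with
columns z-scored internally and the penalty scaled by the mean diagonal of
the standardized Gram matrix, so λ is dimensionless; coefficients are
returned in original units. λ = 0 reproduces OLS; collinear designs at
λ = 0 raise an error advising λ > 0.

Prediction accuracy is 10-fold cross-validated Pearson r: contiguous time
blocks (avoiding leakage through autocorrelation), per fold ~80% training,
one block validation, one block test; λ is chosen per fold from a
logarithmic grid 10⁻⁷…10⁷ (one point per decade) by validation r, and test
r is Fisher-z averaged across folds. Centering and standardisation are
computed from the training rows only, in Gram space.

The permutation baseline pairs the EEG with circularly time-shifted
predictors (uniform shift, minimum 5 s to avoid near-identity shifts) for
each fold, preserving predictor statistics while destroying alignment; one
shift per fold by default. Circular (not linear) shifting keeps the
duration and run-length structure intact.

The electrode of record for group statistics is the one with the highest
mean observed accuracy across participants and conditions — computed, not
hard-coded.

## Group-level statistics

Accuracy records (per participant × condition, or × feature) are analysed
with linear mixed models (statsmodels): age is mean-centred, language
condition contrast-coded (native = −0.5), participant a random intercept;
per-feature models use the observed-minus-baseline accuracy as dependent
variable with crossed random intercepts for participant and feature
(variance components on a single grouping). t tests use the residual-df
approximation (`df_method="residual"` in every result) — the numerics
stack provides no Satterthwaite df for mixed models; with ≥ 1000
observations the difference is negligible. Likelihood-ratio comparisons
(pitch-similarity addition; log/quadratic/cubic age terms) use ML fits, as
REML likelihoods are not comparable across fixed-effect structures; Wald
terms are reported from REML fits. If the pitch-similarity rank adds no
column-space beyond the duration terms (e.g. identical columns), the LR
statistic is exactly 0 and the VIFs are reported as infinite.

The *divergence age* is the smallest age on a 1-month grid over the
observed range at which the pointwise 95% CI of the fitted mean difference
(native − non-native, or observed − baseline) lies above zero; the CI is of
the conditional mean, not a prediction interval, matching the notion of a
fitted age trajectory. The sex-balanced bootstrap redraws equal numbers of
girls and boys with replacement (totalling the original N), refits the
condition model with sex interactions, and reports percentile CIs of the
interaction t values.

A known inferential limitation, deliberate because the models use random
intercepts only: when per-feature *slopes* truly vary across features, the
age × rank test treats 17 features as if they were independent replicates
and is anticonservative. The type-I simulations therefore shuffle ranks in
cohorts with homogeneous feature slopes, the null under which the
random-intercept model is correctly specified.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated:

* **phoneme stream** — each feature's on/off state evolves as a two-state
  Markov chain over ~50 ms phoneme slots (20 phonemes/s; slot durations
  N(50, 10) ms clipped to 30–80 ms), so the joint bundle process is a
  Markov chain and the realized phoneme inventory is the set of distinct
  bundles. Stay probabilities are calibrated by Monte-Carlo bisection so
  the silence-appended merged-run median per feature matches its target —
  defaults are the corpus medians, 68 ms (lateral) to 228 ms (voiced).
  Pauses (p = 0.02 per slot, 100–350 ms) are included in the calibration.
  A rejection loop (≤ 8 draws) enforces 15% accuracy at the study-scale
  450 s duration, with a √duration-widened band for shorter streams where
  a median is intrinsically noisier.
* **pitch** — Gaussian noise low-passed below 3 Hz (modulation power
  < 4 Hz, the prosodic scale), mapped to 220 ± 35 Hz and clipped to
  75–600 Hz, gated by voicing; a coupling parameter blends the [voiced]
  feature gate (coupling 1) with an independent matched-statistics gate
  (coupling 0).
* **EEG** — sum over predictors of kernel⊛predictor × gain plus 1/f noise;
  kernels are differences of gammas peaking ~100–200 ms (infant
  auditory-response-like), zero at negative lags; channels receive a fixed
  mixing profile, SNR is defined at the strongest channel. Spikes and flat
  channels can be injected for preprocessing tests.
* **cohort** — 66 children (40 girls), ages uniform on 3–54 months.
  Cohort-level records are drawn at the *summary level*: cross-validated
  accuracies are sampled directly from the accuracy model (the
  distributional endpoint of the signal pipeline), which is what the group
  statistics consume; the *signal level*
  (`generate_participant_signals`) produces raw predictor/EEG pairs for
  kernel-recovery and preprocessing tests. Native accuracy grows linearly
  with age (0.0015 accuracy units/month) and crosses the non-native level
  at 28 months and the permutation baseline at 14 months; non-native
  accuracy is age-flat. Residual SD 0.012, participant SD 0.008, baseline
  SD 0.005 put accuracies on the 0.01–0.06 scale of single-subject speech
  TRFs. These effect sizes are chosen for clear recoverability of the
  generating structure at n = 40–66 (they are stronger than typical infant
  effects; the point of the synthetic cohort is validation of the
  machinery, not emulation of empirical effect magnitudes). Per-feature
  slopes are linear in a configurable rank source (duration rank,
  pitch-similarity rank, or none), 0.00012 accuracy units/month per rank
  step around the mean slope 0.0008.

Every dataset carries its `GeneratorConfig` and seed; regeneration is
bit-identical.

### What the synthetic conditions do not show

The generator's phoneme stream has no coarticulation, no lexical
structure, and feature states are independent across features (real
bundles are constrained); its EEG noise is stationary 1/f without ocular
or movement artifacts beyond the injected ones; accuracy records at the
summary level bypass per-feature differences in predictor sparsity.
Passing the acceptance contracts therefore demonstrates correctness and
calibration of the estimation and inference machinery under known ground
truth — not that real infant EEG satisfies the models' assumptions.

## Problem sizes used in the validation suite

Oracle equivalence uses 100 random problems (50–200 samples, 2–6
predictors, 3–11 lags). Kernel recovery uses one 400 s participant at
100 Hz and SNR 10 dB. Null calibration uses 50 replicates of 120 s
zero-coupling recordings. Divergence-age recovery uses 200 cohorts of
n = 40; the dissociation contracts use 200 cohorts per scenario (100 in
the summary script) at n = 66; type-I rates use 200 replicates per model.
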