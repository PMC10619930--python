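# phonotrf

Forward-encoding ("deconvolution") analysis of phonological-feature
processing in infant EEG recorded during continuous, naturalistic speech —
for developmental and auditory neuroscientists who want to trace how the
feature-based phoneme representation emerges across the first years of
life.

The pipeline covers the full path from speech annotations to group-level
inference:

* **Feature predictors** — phoneme-level forced-alignment output (Praat
  TextGrid or TSV) is mapped through a Chomsky–Halle lexicon to 17 binary
  phonological features (voiced, continuant, sonorant, … lateral) and
  rasterized into step-function predictors; 16-band log-spaced spectrogram
  (250–8000 Hz) and autocorrelation F0 track complete the predictor set.
* **Corpus statistics** — each feature's *feature-continuous stretch*
  duration (median over maximal multi-phoneme runs, with following silence
  appended), its duration rank, occurrence rank, and similarity to the
  pitch track (max |normalized cross-correlation| within ±500 ms).
* **Infant-EEG preprocessing** — an automatic (HAPPE-style) chain:
  zero-phase FIR band-pass, flat/Hurst/log-power bad-channel rules,
  level-13 wavelet artifact thresholding, spherical-spline interpolation,
  linked-mastoid re-referencing, ±200 μV epoch rejection with zero-padded
  recombination.
* **TRF engine** — the temporal response function w(lag, predictor,
  electrode), lags −150…400 ms, estimated by ridge regression

      ŵ = argmin‖Y − Xw‖² + λ‖w‖²

  on the lag-expanded design matrix; 10-fold cross-validated prediction
  accuracy (Pearson r between predicted and held-out EEG, λ tuned per fold
  on a 10⁻⁷…10⁷ grid) and a permutation baseline from circularly
  time-shifted predictors.
* **Group statistics** — linear mixed models of accuracy with age ×
  condition (native = −0.5) and participant random intercepts; per-feature
  models of observed-minus-baseline accuracy with age × duration-rank and
  age × pitch-similarity-rank fixed effects and crossed participant/feature
  intercepts; divergence age from the fitted 95% CI of an accuracy
  difference; sex-balanced bootstrap CIs.
* **Synthetic data** — a generator with known ground truth: Markov phoneme
  streams calibrated to realistic feature run-lengths (68–228 ms medians),
  <4 Hz pitch contours, EEG simulated by kernel convolution plus 1/f
  noise, and cross-sectional cohorts (66 children, 3–54 months) with
  configurable age-gain structure.

## Worked example

```python
import numpy as np
from phonotrf.synth import GeneratorConfig, generate_participant_signals, generate_cohort
from phonotrf.trf import cross_validate, permutation_baseline, ridge_fit
from phonotrf.group import fit_condition_age_model, divergence_age

# one simulated participant: 400 s of speech-feature predictors and EEG
cfg = GeneratorConfig(duration_s=400, snr_db=10.0, seed=5, n_channels=2)
pred, eeg, truth = generate_participant_signals(cfg, n_features=3)

cv = cross_validate(pred.data, eeg, cfg.fs)
base = permutation_baseline(pred.data, eeg, cfg.fs, rng=1)
print("accuracy", cv.accuracy.round(3), "baseline", base.accuracy.round(3))

model = ridge_fit(pred.data, eeg, float(np.median(cv.best_lambda)),
                  fs=cfg.fs, lag_window_ms=cfg.lag_window_ms)
r = np.corrcoef(model.kernel(0, 0), truth.kernels[:, 0])[0, 1]
print("kernel recovery r =", round(r, 3))

# a synthetic cohort: native accuracy grows with age, non-native is flat
records, _ = generate_cohort(GeneratorConfig(seed=1))
res = fit_condition_age_model(records)
print("age x condition t =", round(res.terms.loc["age_c:condition_code", "t"], 2))
print("divergence age:", divergence_age(records, "condition"), "months")
```

prints

```
accuracy [0.961 0.662] baseline [-0.005 -0.003]
kernel recovery r = 0.998
age x condition t = -12.91
divergence age: 32.0 months
```

The driven electrode reaches cross-validated accuracy 0.96 while the
time-shifted baseline sits at zero; the estimated TRF kernel matches the
generating kernel almost perfectly at 10 dB SNR. In the cohort, the
age × condition interaction is reliably detected (its sign reflects the
contrast coding: the native condition, coded −0.5, gains with age), and the
fitted CI of the native-minus-non-native difference clears zero at 32
months against a generating crossover of 28 months.

A thin CLI exposes the same functionality (`phonotrf corpus-stats`,
`phonotrf synth`, `phonotrf fit-trf`, `phonotrf group-stats`).

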