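"""Synthetic speech-like predictors and simulated EEG with known ground truth.

The generator emulates the study conditions the pipeline is built for:

* a phoneme stream at ~20 phonemes/s (mean duration ~50 ms) whose
  per-feature merged-run median durations are calibrated to configurable
  targets (defaults: the corpus medians, 68-228 ms across the 17 features);
* a smooth F0 contour with modulation power below 4 Hz, gated by voicing
  with configurable coupling to the [voiced] feature;
* EEG formed by convolving each predictor with a difference-of-gammas
  kernel inside the -150..400 ms lag window, scaled by a participant gain,
  mixed into channels, plus 1/f noise at a configurable SNR;
* a cross-sectional cohort (default 66 children, 40 female, 3-54 months)
  whose native-language prediction accuracy grows with age while the
  non-native accuracy stays flat, with configurable crossover ages for the
  condition difference (default 28 months) and the difference from the
  permutation baseline (default 14 months).

Every dataset carries its :class:`GeneratorConfig` and seed; regeneration
with the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .lexicon import FEATURES, FeatureLexicon, Interval, PhonemeAnnotation
from .predictors import PredictorSet
from .trf import lag_design_matrix, lag_samples, DEFAULT_LAG_WINDOW_MS

#: Default per-feature merged-run median durations (ms), longest to shortest.
RUN_MEDIANS_MS: dict[str, float] = {
    "voiced": 228.0, "continuant": 197.0, "sonorant": 178.0, "low": 132.0,
    "tense": 121.0, "back": 120.0, "strident": 116.0, "consonantal": 116.0,
    "long": 110.0, "syllabic": 109.0, "round": 109.0, "high": 102.0,
    "coronal": 92.0, "anterior": 90.0, "nasal": 70.0, "labial": 69.0,
    "lateral": 68.0,
}

#: Default feature->pitch-similarity rank (1 = least similar).
PITCH_SIMILARITY_RANK: dict[str, int] = {
    "voiced": 17, "continuant": 15, "sonorant": 16, "low": 5, "tense": 10,
    "back": 12, "strident": 2, "consonantal": 13, "long": 6, "syllabic": 14,
    "round": 4, "high": 8, "coronal": 9, "anterior": 11, "nasal": 7,
    "labial": 3, "lateral": 1,
}

#: Default feature->occurrence rank (1 = least frequent).
OCCURRENCE_RANK: dict[str, int] = {
    "voiced": 17, "continuant": 15, "sonorant": 16, "low": 5, "tense": 8,
    "back": 11, "strident": 4, "consonantal": 14, "long": 2, "syllabic": 12,
    "round": 3, "high": 9, "coronal": 10, "anterior": 13, "nasal": 6,
    "labial": 7, "lateral": 1,
}

DURATION_RANK: dict[str, int] = {
    f: r + 1
    for r, f in enumerate(sorted(RUN_MEDIANS_MS, key=lambda f: RUN_MEDIANS_MS[f]))
}


class GeneratorConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic cohort.

    Accuracy-model defaults place prediction accuracies on the 0.01-0.05
    scale typical of single-subject speech-TRF models, with the native
    accuracy growing linearly in age and the non-native accuracy age-flat.
    """

    n_participants: int = 66
    n_female: int = 40
    age_range_months: tuple[float, float] = (3.0, 54.0)
    fs: float = 100.0
    duration_s: float = 450.0
    # phoneme stream
    feature_run_medians_ms: dict[str, float] = field(
        default_factory=lambda: dict(RUN_MEDIANS_MS))
    phoneme_mean_s: float = 0.05
    phoneme_sd_s: float = 0.01
    pause_prob: float = 0.02
    pause_range_s: tuple[float, float] = (0.10, 0.35)
    always_on: tuple[str, ...] = ()
    # pitch
    pitch_coupling: float = 1.0
    pitch_mod_hz: float = 3.0
    pitch_mean_hz: float = 220.0
    pitch_sd_hz: float = 35.0
    # EEG forward model
    lag_window_ms: tuple[float, float] = DEFAULT_LAG_WINDOW_MS
    snr_db: float = 0.0
    noise_exponent: float = 1.0
    n_channels: int = 4
    # cohort accuracy model
    crossover_condition_months: float = 28.0
    crossover_baseline_months: float = 14.0
    slope_per_month: float = 0.0015
    sd_participant: float = 0.008
    sd_residual: float = 0.012
    sd_baseline: float = 0.005
    # per-feature accuracy model
    feature_intercept: float = 0.01
    feature_slope_mean: float = 0.0008
    feature_slope_per_rank: float = 0.00012
    slope_rank_source: str = "duration"  # "duration" | "pitch_similarity" | "none"
    pitch_rank_mode: str = "table"       # "table" | "decoupled"
    sd_feature: float = 0.004
    sd_feature_residual: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.feature_run_medians_ms.values()):
            raise GeneratorConfigError("run-median targets must be positive")
        if not np.isfinite(self.snr_db):
            raise GeneratorConfigError("SNR must be finite")
        if not 0 <= self.n_female <= self.n_participants:
            raise GeneratorConfigError("n_female out of range")
        infeasible = {
            f: v for f, v in self.feature_run_medians_ms.items()
            if v < 0.9 * self.phoneme_mean_s * 1000
        }
        if infeasible:
            raise GeneratorConfigError(
                f"run medians below the phoneme duration are infeasible: {infeasible}")


# ---------------------------------------------------------------------------
# Phoneme stream
# ---------------------------------------------------------------------------

def _run_duration_median(p_stay: float, mean_s: float, sd_s: float,
                         rng: np.random.Generator, n: int = 6000,
                         pause_prob: float = 0.0,
                         pause_range_s: tuple[float, float] = (0.1, 0.35)) -> float:
    """Monte-Carlo median duration of a run of geometric(p_stay) slots,
    including the occasional appended pause after the run's last slot."""
    k = rng.geometric(1.0 - p_stay, size=n)
    durs = k * mean_s + np.sqrt(k) * sd_s * rng.standard_normal(n)
    if pause_prob > 0:
        hit = rng.random(n) < pause_prob
        durs = durs + hit * rng.uniform(*pause_range_s, size=n)
    return float(np.median(durs))


def _calibrate_stay_prob(target_s: float, mean_s: float, sd_s: float,
                         seed: int, pause_prob: float = 0.0,
                         pause_range_s: tuple[float, float] = (0.1, 0.35)) -> float:
    """Bisection on the stay probability so run-median matches the target."""
    lo, hi = 0.005, 0.995

    def median_at(p: float) -> float:
        return _run_duration_median(p, mean_s, sd_s,
                                    np.random.default_rng(seed + 1),
                                    pause_prob=pause_prob,
                                    pause_range_s=pause_range_s)

    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if median_at(mid) < target_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _occupancy_for(feature: str) -> float:
    """Stationary on-fraction per feature, increasing with occurrence rank."""
    rank = OCCURRENCE_RANK.get(feature, 9)
    return 0.15 + 0.45 * (rank - 1) / 16.0


def generate_phoneme_stream(
    cfg: GeneratorConfig, rng: np.random.Generator | int | None = None
) -> tuple[PhonemeAnnotation, FeatureLexicon]:
    """Markov phoneme stream whose per-feature run medians match the config.

    Each 17-bit feature state evolves as an independent two-state Markov
    chain over ~50 ms phoneme slots (the joint process is a Markov chain on
    bundles); stay probabilities are calibrated so the median merged-run
    duration per feature matches ``cfg.feature_run_medians_ms``.  Occasional
    pauses are inserted between phonemes.  A lexicon is built from the
    distinct bundles encountered.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    features = tuple(cfg.feature_run_medians_ms)
    max_tries = 8
    # 15% contract at the study-scale duration; the sampling error of a
    # median shrinks with the number of runs, so shorter streams get a
    # proportionally wider acceptance band
    tol = 0.15 * max(1.0, np.sqrt(450.0 / cfg.duration_s))
    for attempt in range(max_tries):
        ann, lex = _sample_stream(cfg, rng, features)
        if _medians_within(ann, lex, cfg, tol=tol):
            return ann, lex
    raise GeneratorConfigError(
        "could not calibrate run medians to the configured targets within "
        f"{100 * tol:.0f}% after {max_tries} attempts")


def _medians_within(ann, lex, cfg: GeneratorConfig, tol: float) -> bool:
    from .corpus import median_feature_duration
    from .lexicon import expand_features

    med = median_feature_duration(expand_features(ann, lex))
    for f, target in cfg.feature_run_medians_ms.items():
        if f in cfg.always_on:
            continue
        if not np.isfinite(med[f]) or abs(med[f] - target) / target > tol:
            return False
    return True


def _sample_stream(cfg: GeneratorConfig, rng: np.random.Generator,
                   features: tuple[str, ...]):
    n_slots = int(np.ceil(cfg.duration_s / cfg.phoneme_mean_s))

    states = np.zeros((n_slots, len(features)), dtype=int)
    for j, feat in enumerate(features):
        if feat in cfg.always_on:
            states[:, j] = 1
            continue
        target = cfg.feature_run_medians_ms[feat] / 1000.0
        p_on = _calibrate_stay_prob(target, cfg.phoneme_mean_s, cfg.phoneme_sd_s,
                                    seed=1_000_003 + 7 * j,
                                    pause_prob=cfg.pause_prob,
                                    pause_range_s=cfg.pause_range_s)
        occ = _occupancy_for(feat)
        p_off = float(np.clip(1.0 - occ / (1.0 - occ) * (1.0 - p_on), 0.01, 0.995))
        s = int(rng.random() < occ)
        for t in range(n_slots):
            states[t, j] = s
            stay = p_on if s else p_off
            if rng.random() >= stay:
                s = 1 - s
    # de-duplicate bundles into labels
    table: dict[str, np.ndarray] = {}
    bundle_label: dict[tuple, str] = {}
    labels = []
    for t in range(n_slots):
        key = tuple(states[t])
        if key not in bundle_label:
            name = f"p{len(bundle_label):03d}"
            bundle_label[key] = name
            table[name] = np.array(key, dtype=int)
        labels.append(bundle_label[key])

    durs = np.clip(rng.normal(cfg.phoneme_mean_s, cfg.phoneme_sd_s, n_slots),
                   0.6 * cfg.phoneme_mean_s, 1.6 * cfg.phoneme_mean_s)
    pauses = rng.random(n_slots) < cfg.pause_prob
    pause_durs = rng.uniform(*cfg.pause_range_s, size=n_slots)

    intervals = []
    t = 0.0
    for i in range(n_slots):
        intervals.append(Interval(labels[i], t, t + durs[i]))
        t += durs[i]
        if pauses[i]:
            t += pause_durs[i]
    ann = PhonemeAnnotation(intervals=intervals, total_duration=t)
    lex = FeatureLexicon(features=features, table=table)
    return ann, lex


# ---------------------------------------------------------------------------
# Pitch
# ---------------------------------------------------------------------------

def _smooth_contour(n: int, fs: float, mod_hz: float,
                    rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n + int(4 * fs))
    b, a = sps.butter(4, mod_hz, btype="low", fs=fs)
    x = sps.filtfilt(b, a, noise)[int(2 * fs):int(2 * fs) + n]
    return (x - x.mean()) / (x.std() or 1.0)


def generate_pitch(
    cfg: GeneratorConfig,
    voiced: np.ndarray | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> PredictorSet:
    """Smooth (<4 Hz) F0 contour with voicing gating.

    ``cfg.pitch_coupling`` controls how strongly the voiced/unvoiced gate
    follows the [voiced] feature column: 1 copies it, 0 uses an independent
    gate with matched run statistics.
    """
    rng = np.random.default_rng(cfg.seed + 17 if rng is None else rng)
    if n_samples is None:
        n_samples = voiced.size if voiced is not None else int(cfg.duration_s * cfg.fs)
    contour = _smooth_contour(n_samples, cfg.fs, cfg.pitch_mod_hz, rng)
    f0 = np.clip(cfg.pitch_mean_hz + cfg.pitch_sd_hz * contour, 75.0, 600.0)

    # independent gate with voiced-like run statistics
    slot = max(int(round(cfg.phoneme_mean_s * cfg.fs)), 1)
    target = RUN_MEDIANS_MS["voiced"] / 1000.0
    p_on = _calibrate_stay_prob(target, cfg.phoneme_mean_s, cfg.phoneme_sd_s,
                                seed=2_000_003)
    occ = _occupancy_for("voiced")
    p_off = float(np.clip(1.0 - occ / (1.0 - occ) * (1.0 - p_on), 0.01, 0.995))
    gate_ind = np.zeros(n_samples)
    s = 1
    for start in range(0, n_samples, slot):
        gate_ind[start:start + slot] = s
        stay = p_on if s else p_off
        if rng.random() >= stay:
            s = 1 - s

    if voiced is None:
        gate = gate_ind
    else:
        voiced = np.asarray(voiced, dtype=float).ravel()[:n_samples]
        block = max(int(round(0.5 * cfg.fs)), 1)
        gate = np.empty(n_samples)
        for start in range(0, n_samples, block):
            src = voiced if rng.random() < cfg.pitch_coupling else gate_ind
            gate[start:start + block] = src[start:start + block]
    return PredictorSet((f0 * gate)[:, None], cfg.fs, ["f0"], "pitch")


# ---------------------------------------------------------------------------
# EEG forward model
# ---------------------------------------------------------------------------

def gamma_kernel(
    fs: float,
    lag_window_ms=DEFAULT_LAG_WINDOW_MS,
    peak_ms: float = 130.0,
    trough_ms: float = 260.0,
    trough_ratio: float = 0.5,
) -> np.ndarray:
    """Difference-of-gammas TRF kernel on the lag grid, unit peak height.

    Positive deflection peaking near ``peak_ms`` minus a slower negative
    deflection near ``trough_ms`` — an infant auditory-response-like shape.
    Zero at negative lags.
    """
    lags_ms = lag_samples(lag_window_ms, fs) / fs * 1000.0
    t = np.maximum(lags_ms, 0.0)

    def gamma_bump(peak: float, shape: float = 4.0) -> np.ndarray:
        scale = peak / (shape - 1)
        g = (t / scale) ** (shape - 1) * np.exp(-t / scale)
        return g / (g.max() or 1.0)

    k = gamma_bump(peak_ms) - trough_ratio * gamma_bump(trough_ms, shape=5.0)
    if lag_window_ms[0] < 0:
        k[lags_ms < 0] = 0.0
    return k / (np.abs(k).max() or 1.0)


def make_kernels(
    n_predictors: int,
    fs: float,
    lag_window_ms=DEFAULT_LAG_WINDOW_MS,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Stack of per-predictor kernels (lags x predictors) with jittered peaks."""
    rng = np.random.default_rng(rng)
    cols = []
    for _ in range(n_predictors):
        peak = rng.uniform(100.0, 200.0)
        trough = peak + rng.uniform(80.0, 150.0)
        cols.append(gamma_kernel(fs, lag_window_ms, peak, trough,
                                 trough_ratio=rng.uniform(0.3, 0.7)))
    return np.column_stack(cols)


def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent noise, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / (x.std() or 1.0)


@dataclass
class GroundTruth:
    """Generating kernels/gains shipped alongside every simulated dataset."""

    kernels: np.ndarray                  # (lags, predictors)
    gains: np.ndarray                    # (predictors,)
    mixing: np.ndarray                   # (channels,)
    lag_window_ms: tuple[float, float]
    fs: float
    config: GeneratorConfig | None = None
    seed: int | None = None
    duration_rank: dict[str, int] = field(default_factory=dict)
    pitch_similarity_rank: dict[str, int] = field(default_factory=dict)


def simulate_eeg(
    pred: PredictorSet,
    truth: GroundTruth,
    cfg: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
    spikes: list[tuple[int, float]] | None = None,
    flat_channels: list[int] | None = None,
) -> np.ndarray:
    """EEG (samples x channels, uV) = kernels * predictors + 1/f noise.

    The source signal is the sum over predictors of the lagged convolution
    with each generating kernel times its gain; channels receive the source
    scaled by ``truth.mixing`` plus independent pink noise at ``cfg.snr_db``
    (defined at the strongest channel).  Optional artifacts: ``spikes`` is a
    list of (1 s epoch index, amplitude uV); ``flat_channels`` lists channel
    indices to zero out.
    """
    n_lags = lag_samples(truth.lag_window_ms, truth.fs).size
    if truth.kernels.shape[0] != n_lags:
        raise ValueError("kernel longer than the lag window")
    rng = np.random.default_rng(cfg.seed + 31 if rng is None else rng)
    D = lag_design_matrix(pred.data, truth.fs, truth.lag_window_ms)
    w = (truth.kernels * truth.gains[None, :]).reshape(-1)
    source = D @ w
    n = source.size
    sig_sd = source.std() or 1.0
    noise_sd = sig_sd * np.abs(truth.mixing).max() / (10 ** (cfg.snr_db / 20.0))
    eeg = np.empty((n, truth.mixing.size))
    for c in range(truth.mixing.size):
        eeg[:, c] = truth.mixing[c] * source + \
            noise_sd * pink_noise(n, rng, cfg.noise_exponent)
    ep = int(round(truth.fs))
    for epoch, amp in spikes or ():
        eeg[epoch * ep + ep // 2, :] += amp
    for c in flat_channels or ():
        eeg[:, c] = 0.0
    return eeg


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _cohort_frame(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    ages = rng.uniform(*cfg.age_range_months, size=cfg.n_participants)
    sexes = np.array(["F"] * cfg.n_female +
                     ["M"] * (cfg.n_participants - cfg.n_female))
    rng.shuffle(sexes)
    return pd.DataFrame({
        "participant": [f"s{i:03d}" for i in range(cfg.n_participants)],
        "age_months": ages,
        "sex": sexes,
    })


def generate_cohort(
    cfg: GeneratorConfig,
    rng: np.random.Generator | int | None = None,
    per_feature: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cross-sectional accuracy records with known generating structure.

    Summary-level generator: per participant the cross-validated prediction
    accuracies are drawn directly from the cohort accuracy model (linear
    age-gain for the native condition, age-flat non-native, permutation
    baseline centred on zero) — the distributional endpoint of the full
    signal pipeline, suitable for the group-level statistics.  With
    ``per_feature`` one row per feature and condition='native' is produced,
    with the feature slope tied to the configured rank source.

    Returns the records table and a :class:`GroundTruth` carrying the ranks
    and configuration.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    base = _cohort_frame(cfg, rng)
    age_c = base["age_months"] - base["age_months"].mean()
    u = rng.normal(0, cfg.sd_participant, cfg.n_participants)

    if cfg.pitch_rank_mode == "decoupled":
        ranks = np.array([PITCH_SIMILARITY_RANK[f] for f in FEATURES])
        rng.shuffle(ranks)
        pitch_rank = {f: int(r) for f, r in zip(FEATURES, ranks)}
    else:
        pitch_rank = dict(PITCH_SIMILARITY_RANK)
    truth = GroundTruth(
        kernels=np.zeros((0, 0)), gains=np.zeros(0), mixing=np.zeros(0),
        lag_window_ms=cfg.lag_window_ms, fs=cfg.fs, config=cfg, seed=cfg.seed,
        duration_rank=dict(DURATION_RANK), pitch_similarity_rank=pitch_rank,
    )

    if not per_feature:
        n = cfg.n_participants
        age = base["age_months"].to_numpy()
        diff_base = cfg.slope_per_month * (age - cfg.crossover_baseline_months)
        r_base_nat = rng.normal(0.0, cfg.sd_baseline, n)
        r_base_non = rng.normal(0.0, cfg.sd_baseline, n)
        nat = r_base_nat + diff_base + u + rng.normal(0, cfg.sd_residual, n)
        # non-native flat in age; offset sets the condition crossover
        non = (cfg.slope_per_month
               * (cfg.crossover_condition_months - cfg.crossover_baseline_months)
               + u + rng.normal(0, cfg.sd_residual, n))
        both = pd.concat([base, base], ignore_index=True)
        both["condition"] = ["native"] * n + ["nonnative"] * n
        both["condition_code"] = [-0.5] * n + [0.5] * n
        both["electrode"] = "FC5"
        both["r_observed"] = np.concatenate([nat, non])
        both["r_baseline"] = np.concatenate([r_base_nat, r_base_non])
        order = np.argsort(both["participant"].to_numpy(), kind="stable")
        return both.iloc[order].reset_index(drop=True), truth

    rank_of = {
        "duration": truth.duration_rank,
        "pitch_similarity": truth.pitch_similarity_rank,
        "none": {f: 9 for f in FEATURES},
    }[cfg.slope_rank_source]
    v = rng.normal(0, cfg.sd_feature, len(FEATURES))
    n, m = cfg.n_participants, len(FEATURES)
    ranks = np.array([rank_of[f] for f in FEATURES], dtype=float)
    slopes = cfg.feature_slope_mean + cfg.feature_slope_per_rank * (ranks - 9)
    age_c_arr = np.asarray(age_c, dtype=float)
    diff = (cfg.feature_intercept
            + slopes[None, :] * age_c_arr[:, None]
            + u[:, None] + v[None, :]
            + rng.normal(0, cfg.sd_feature_residual, (n, m)))
    r_base = rng.normal(0.0, cfg.sd_baseline, (n, m))
    out = base.loc[base.index.repeat(m)].reset_index(drop=True)
    out["condition"] = "native"
    out["condition_code"] = -0.5
    out["electrode"] = "FC5"
    out["feature"] = list(FEATURES) * n
    out["duration_rank"] = [truth.duration_rank[f] for f in FEATURES] * n
    out["occurrence_rank"] = [OCCURRENCE_RANK[f] for f in FEATURES] * n
    out["pitch_similarity_rank"] = [pitch_rank[f] for f in FEATURES] * n
    out["r_observed"] = (r_base + diff).ravel()
    out["r_baseline"] = r_base.ravel()
    return out, truth


def generate_participant_signals(
    cfg: GeneratorConfig,
    gain: float = 1.0,
    n_features: int = 3,
    rng: np.random.Generator | int | None = None,
) -> tuple[PredictorSet, np.ndarray, GroundTruth]:
    """Signal-level dataset: feature predictors, simulated EEG, ground truth.

    Uses the first ``n_features`` features of the generated stream as
    predictors and a per-predictor difference-of-gammas kernel; channel 0
    carries the strongest projection of the source.
    """
    from .lexicon import expand_features
    from .predictors import build_feature_predictor

    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    ann, lex = generate_phoneme_stream(cfg, rng)
    spans = expand_features(ann, lex)
    feats = tuple(lex.features[:n_features])
    n_samples = int(round(ann.total_duration * cfg.fs))
    pred = build_feature_predictor(
        {f: spans[f] for f in feats}, fs=cfg.fs, n_samples=n_samples,
        features=feats)
    kernels = make_kernels(n_features, cfg.fs, cfg.lag_window_ms, rng)
    mixing = np.linspace(1.0, 0.25, cfg.n_channels)
    truth = GroundTruth(kernels=kernels,
                        gains=np.full(n_features, gain),
                        mixing=mixing, lag_window_ms=cfg.lag_window_ms,
                        fs=cfg.fs, config=cfg, seed=cfg.seed,
                        duration_rank=dict(DURATION_RANK),
                        pitch_similarity_rank=dict(PITCH_SIMILARITY_RANK))
    eeg = simulate_eeg(pred, truth, cfg, rng)
    return pred, eeg, truth
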