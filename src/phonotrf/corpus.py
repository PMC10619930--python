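"""Feature-timing statistics of a speech corpus.

For each phonological feature this module computes the median duration of
its feature-continuous stretches (silence-appended), its rank among features
from shortest to longest, its occurrence rank from least to most frequent,
and its similarity to the pitch track (maximum absolute normalized
cross-correlation within a +/-500 ms lag range), ranked from least to most
similar.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .lexicon import (
    FEATURES,
    FeatureIntervalSet,
    FeatureLexicon,
    PhonemeAnnotation,
    expand_features,
    span_durations_ms,
)
from .predictors import PredictorSet, build_feature_predictor

#: Default lag range for the pitch-similarity cross-correlation, seconds.
MAX_LAG_S = 0.5


def median_feature_duration(spans: FeatureIntervalSet) -> dict[str, float]:
    """Median span duration per feature, in ms; NaN for span-less features."""
    return {
        feat: float(np.median(span_durations_ms(sp))) if sp else float("nan")
        for feat, sp in spans.items()
    }


def rank_features(
    values: dict[str, float],
    order: tuple[str, ...] | None = None,
) -> dict[str, int]:
    """Rank features ascending: rank 1 = smallest value.

    Ties are broken deterministically by the canonical feature order
    (``order``, default the canonical feature list restricted to the keys
    of ``values``).
    """
    if order is None:
        order = tuple(f for f in FEATURES if f in values) or tuple(values)
    missing = [f for f in order if not np.isfinite(values[f])]
    if missing:
        raise ValueError(f"missing value for feature(s): {missing}")
    idx = {f: i for i, f in enumerate(order)}
    ordered = sorted(order, key=lambda f: (values[f], idx[f]))
    return {f: r + 1 for r, f in enumerate(ordered)}


def occurrence_counts(
    ann: PhonemeAnnotation, lex: FeatureLexicon
) -> dict[str, int]:
    """Count feature-positive phoneme tokens per feature."""
    counts = np.zeros(len(lex.features), dtype=int)
    for iv in ann.intervals:
        counts += lex.bundle(iv.label)
    return {f: int(c) for f, c in zip(lex.features, counts)}


def cross_correlation_score(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag_s: float = MAX_LAG_S,
    zero_lag_only: bool = False,
) -> tuple[float, float]:
    """Max-|.| normalized cross-correlation of two z-scored series.

    Returns ``(score, lag_s)`` where positive ``lag_s`` means ``y`` lags
    ``x``.  The score is the signed correlation value at the lag of maximum
    absolute correlation within ``+/-max_lag_s``; it lies in [-1, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("series must have equal length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant series")
    xz = (x - x.mean()) / sx
    yz = (y - y.mean()) / sy
    n = x.size
    if zero_lag_only:
        return float(xz @ yz / n), 0.0
    max_lag = int(round(max_lag_s * fs))
    full = sps.correlate(yz, xz, mode="full") / n
    lags = sps.correlation_lags(n, n, mode="full")
    sel = np.abs(lags) <= max_lag
    c, l = full[sel], lags[sel]
    k = int(np.argmax(np.abs(c)))
    return float(c[k]), float(l[k] / fs)


def pitch_similarity(
    feature_col: np.ndarray,
    pitch_col: np.ndarray,
    fs: float,
    max_lag_s: float = MAX_LAG_S,
    zero_lag_only: bool = False,
    interpolate_unvoiced: bool = False,
) -> float:
    """Similarity between a feature step function and the F0 track.

    By default the raw pitch track (zeros in unvoiced frames) is used;
    ``interpolate_unvoiced`` linearly interpolates F0 through unvoiced gaps
    first.
    """
    pitch = np.asarray(pitch_col, dtype=float).ravel()
    if interpolate_unvoiced:
        voiced = pitch > 0
        if 0 < voiced.sum() < pitch.size:
            idx = np.arange(pitch.size)
            pitch = np.interp(idx, idx[voiced], pitch[voiced])
    score, _ = cross_correlation_score(
        feature_col, pitch, fs, max_lag_s=max_lag_s, zero_lag_only=zero_lag_only)
    return score


def feature_stats(
    ann: PhonemeAnnotation,
    lex: FeatureLexicon,
    pitch: PredictorSet | None = None,
) -> pd.DataFrame:
    """Per-feature duration/occurrence(/pitch-similarity) summary table.

    Returns a DataFrame indexed by feature with columns ``median_ms``,
    ``duration_rank``, ``occurrence_rank`` and, when a pitch track is given,
    ``pitch_similarity`` and ``pitch_similarity_rank``.  Features with no
    occurrence in the corpus are excluded from ranking with a warning.
    """
    spans = expand_features(ann, lex)
    medians = median_feature_duration(spans)
    counts = occurrence_counts(ann, lex)
    present = tuple(f for f in lex.features if counts[f] > 0)
    absent = [f for f in lex.features if counts[f] == 0]
    if absent:
        warnings.warn(f"features with zero occurrences excluded: {absent}")

    med = {f: medians[f] for f in present}
    occ = {f: float(counts[f]) for f in present}
    dur_rank = rank_features(med, order=present)
    occ_rank = rank_features(occ, order=present)

    out = pd.DataFrame({
        "median_ms": pd.Series(med),
        "duration_rank": pd.Series(dur_rank),
        "occurrence_count": pd.Series({f: counts[f] for f in present}),
        "occurrence_rank": pd.Series(occ_rank),
    }).loc[list(present)]
    out.index.name = "feature"

    if pitch is not None:
        feats = build_feature_predictor(
            spans, fs=pitch.fs, n_samples=pitch.n_samples, features=present)
        sims = {
            f: pitch_similarity(feats.data[:, j], pitch.data[:, 0], pitch.fs)
            for j, f in enumerate(present)
        }
        sim_rank = rank_features({f: abs(s) for f, s in sims.items()}, order=present)
        out["pitch_similarity"] = pd.Series(sims)
        out["pitch_similarity_rank"] = pd.Series(sim_rank)
    return out
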