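"""Time-aligned predictor matrices for forward encoding models.

All predictors are sampled at a common analysis rate (default 100 Hz, well
above twice the 10 Hz edge of the EEG analysis band):

* ``features`` — 17 binary step functions, one per phonological feature,
  that are 1 while the feature is active in the speech stream;
* ``spectrogram`` — 16 non-negative band envelopes with centre frequencies
  log-spaced between 250 and 8000 Hz;
* ``pitch`` — a single fundamental-frequency (F0) track in Hz, 0 where the
  signal is unvoiced, estimated by the autocorrelation method with a
  75–600 Hz search range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .lexicon import FEATURES, FeatureIntervalSet

#: Default analysis sampling rate in Hz.
FS_ANALYSIS = 100.0

KINDS = ("features", "spectrogram", "pitch")


@dataclass
class PredictorSet:
    """Aligned multichannel predictor time series.

    ``data`` has shape (samples, predictors); ``kind`` fixes the column
    contract (see module docstring).
    """

    data: np.ndarray
    fs: float
    names: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.names):
            raise ValueError("names length must match number of columns")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "features":
            if not np.isin(self.data, (0.0, 1.0)).all():
                raise ValueError("feature predictors must be binary")
        elif self.kind == "spectrogram":
            if self.data.shape[1] != 16:
                raise ValueError("spectrogram must have 16 bands")
            if (self.data < 0).any():
                raise ValueError("spectrogram envelopes must be non-negative")
        elif self.kind == "pitch":
            if self.data.shape[1] != 1:
                raise ValueError("pitch predictor has exactly one column")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV with a JSON sidecar (fs, names, kind)."""
        path = Path(path)
        pd.DataFrame(self.data, columns=self.names).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            {"fs": self.fs, "names": self.names, "kind": self.kind}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictorSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path)
        return cls(df.to_numpy(float), meta["fs"], list(meta["names"]), meta["kind"])


def build_feature_predictor(
    spans: FeatureIntervalSet,
    fs: float = FS_ANALYSIS,
    n_samples: int | None = None,
    features: tuple[str, ...] = FEATURES,
) -> PredictorSet:
    """Rasterize per-feature spans into binary step functions.

    Column *f* is 1 at samples whose time lies inside any active span of
    feature *f*.  Span boundaries are rounded to the nearest sample.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    max_off = max((off for sp in spans.values() for _, off in sp), default=0.0)
    if n_samples is None:
        n_samples = int(round(max_off * fs))
    if max_off * fs > n_samples + 0.5:
        raise ValueError(
            f"span end {max_off:.3f}s exceeds signal length {n_samples / fs:.3f}s")
    data = np.zeros((n_samples, len(features)))
    for j, feat in enumerate(features):
        for onset, offset in spans.get(feat, ()):
            lo = int(np.floor(onset * fs + 0.5))
            hi = int(np.floor(offset * fs + 0.5))
            data[max(lo, 0):min(hi, n_samples), j] = 1.0
    return PredictorSet(data, fs, list(features), "features")


def _log_band_edges(n_bands: int, fmin: float, fmax: float) -> np.ndarray:
    """Band edges with geometrically spaced centres and geometric-midpoint
    edges; the outer edges extend the centre grid by half a step."""
    centers = np.geomspace(fmin, fmax, n_bands)
    ratio = (fmax / fmin) ** (1.0 / (n_bands - 1))
    inner = np.sqrt(centers[:-1] * centers[1:])
    return np.concatenate(([centers[0] / np.sqrt(ratio)], inner,
                           [centers[-1] * np.sqrt(ratio)]))


def build_spectrogram(
    audio: np.ndarray,
    sr: float,
    fs_out: float = FS_ANALYSIS,
    n_samples: int | None = None,
    n_bands: int = 16,
    fmin: float = 250.0,
    fmax: float = 8000.0,
    log_compress: bool = False,
) -> PredictorSet:
    """16-band log-spaced spectrogram envelope (250–8000 Hz).

    Short-time Fourier magnitudes are pooled (power sum, then sqrt) into
    bands whose centres are geometrically spaced, and the band envelopes are
    linearly interpolated onto the analysis sample grid.  ``log_compress``
    applies log(1 + x) to the envelopes.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if sr < 2 * fmax:
        raise ValueError(f"audio sample rate {sr} Hz too low for fmax {fmax} Hz")
    nperseg = int(round(0.025 * sr))
    if audio.size < nperseg:
        raise ValueError("audio shorter than one analysis frame")
    hop = max(int(round(sr / fs_out / 2)), 1)
    freqs, t, Z = signal.stft(audio, fs=sr, nperseg=nperseg,
                              noverlap=nperseg - hop, boundary="zeros")
    power = np.abs(Z) ** 2
    edges = _log_band_edges(n_bands, fmin, fmax)
    bands = np.zeros((n_bands, power.shape[1]))
    for b in range(n_bands):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
        if sel.any():
            bands[b] = power[sel].sum(axis=0)
    env = np.sqrt(bands)
    if n_samples is None:
        n_samples = int(round(audio.size / sr * fs_out))
    t_out = np.arange(n_samples) / fs_out
    out = np.empty((n_samples, n_bands))
    for b in range(n_bands):
        out[:, b] = np.interp(t_out, t, env[b])
    if log_compress:
        out = np.log1p(out)
    names = [f"band_{c:.0f}Hz" for c in np.geomspace(fmin, fmax, n_bands)]
    return PredictorSet(out, fs_out, names, "spectrogram")


def build_pitch_track(
    audio: np.ndarray,
    sr: float,
    fs_out: float = FS_ANALYSIS,
    n_samples: int | None = None,
    fmin: float = 75.0,
    fmax: float = 600.0,
    frame_s: float = 0.04,
    voicing_threshold: float = 0.45,
    silence_threshold: float = 0.01,
) -> PredictorSet:
    """Autocorrelation F0 estimate per analysis frame; unvoiced frames are 0.

    A frame is voiced when its peak normalized autocorrelation in the
    75–600 Hz lag range exceeds ``voicing_threshold`` and its RMS exceeds
    ``silence_threshold`` of the global peak amplitude.  The lag of the peak
    is refined by parabolic interpolation.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if sr < 16000:
        raise ValueError("audio sample rate must be at least 16 kHz")
    frame_len = int(round(frame_s * sr))
    if audio.size < frame_len:
        raise ValueError("audio shorter than one pitch frame")
    if n_samples is None:
        n_samples = int(round(audio.size / sr * fs_out))
    lag_min = int(np.floor(sr / fmax))
    lag_max = int(np.ceil(sr / fmin))
    global_peak = np.abs(audio).max() or 1.0

    f0 = np.zeros(n_samples)
    half = frame_len // 2
    for i in range(n_samples):
        center = int(round(i / fs_out * sr))
        lo, hi = center - half, center + half
        if lo < 0 or hi > audio.size:
            continue
        frame = audio[lo:hi]
        frame = frame - frame.mean()
        rms = np.sqrt(np.mean(frame ** 2))
        if rms < silence_threshold * global_peak:
            continue
        ac = signal.correlate(frame, frame, mode="full")[frame.size - 1:]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        hi_lag = min(lag_max, ac.size - 2)
        if hi_lag <= lag_min:
            continue
        seg = ac[lag_min:hi_lag + 1]
        k = int(np.argmax(seg)) + lag_min
        if ac[k] < voicing_threshold:
            continue
        # parabolic refinement around the peak
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        lag = k + np.clip(delta, -0.5, 0.5)
        hz = sr / lag
        if fmin <= hz <= fmax:
            f0[i] = hz
    return PredictorSet(f0[:, None], fs_out, ["f0"], "pitch")
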