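"""Automatic infant-EEG cleaning and TRF preparation.

The pipeline mirrors an automated (HAPPE-style) approach for infant data
recorded at 500 Hz on a 10/10 montage:

1. zero-phase FIR high-pass above 1 Hz (order 1650, -6 dB at 0.5 Hz) and
   45 Hz low-pass (order 332, -6 dB at 47.5 Hz);
2. bad-channel detection by three rules: flat for >30 consecutive s,
   rescaled-range Hurst exponent < 0.7, and average 1-100 Hz log power
   deviating > 2.75 SD across channels;
3. level-13 wavelet thresholding of large artifacts (coif4, per-level
   universal threshold, detail coefficients clipped at the threshold so the
   super-threshold artifact excess is removed while background EEG passes);
4. spherical-spline interpolation of bad channels (via MNE);
5. re-referencing to the linked mastoids;
6. 1-10 Hz filtering, segmentation into 1 s epochs, rejection of epochs
   whose unfiltered amplitude exceeds +/-200 uV, and recombination with 1 s
   of zeros at discontinuities, applied jointly to EEG and predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal as sps

from .predictors import PredictorSet

#: 28-channel 10/10 EasyCap-style montage; TP9/TP10 are the mastoid sites.
MONTAGE_28 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: 19-channel analysis set (posterior channels excluded); config-driven.
ANALYSIS_19 = (
    "Fz", "F3", "F4", "F7", "F8", "FC5", "FC6", "C3", "C4", "Cz",
    "T7", "T8", "CP5", "CP6", "Pz", "P3", "P4", "P7", "P8",
)

MASTOIDS = ("TP9", "TP10")


class PreprocessError(RuntimeError):
    pass


class InsufficientDataError(PreprocessError):
    """Raised when a participant/condition retains too little clean data."""


@dataclass
class EEGRecording:
    """Multichannel EEG voltage time series in microvolts.

    ``data`` has shape (samples, channels).
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = MONTAGE_28
    bad_channels: set[str] = field(default_factory=set)
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length must match data columns")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not set(self.bad_channels) <= set(self.channel_names):
            raise ValueError("bad_channels must be a subset of channel_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]

    def pick(self, names: tuple[str, ...]) -> "EEGRecording":
        idx = [self.channel_names.index(n) for n in names]
        return replace(self, data=self.data[:, idx], channel_names=tuple(names),
                       bad_channels=self.bad_channels & set(names))


def read_raw(path) -> EEGRecording:
    """Read BrainVision/EDF/FIF raw EEG through MNE into an EEGRecording."""
    import mne

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    data = raw.get_data(picks="eeg") * 1e6  # V -> uV
    return EEGRecording(data.T, raw.info["sfreq"],
                        tuple(raw.copy().pick("eeg").ch_names),
                        set(raw.info["bads"]))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _fir_zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR noncausally (zero phase) along axis 0."""
    out = np.empty_like(data)
    for c in range(data.shape[1]):
        out[:, c] = sps.fftconvolve(data[:, c], taps, mode="same")
    return out


def _scaled_numtaps(order_at_500: int, fs: float) -> int:
    """Filter order stated at 500 Hz, scaled to fs and forced odd."""
    n = int(round(order_at_500 * fs / 500.0)) + 1
    return n if n % 2 == 1 else n + 1


def highpass_taps(fs: float) -> np.ndarray:
    return sps.firwin(_scaled_numtaps(1650, fs), 0.5, pass_zero=False, fs=fs)


def lowpass_taps(fs: float) -> np.ndarray:
    return sps.firwin(_scaled_numtaps(332, fs), 47.5, pass_zero=True, fs=fs)


def bandpass_filters(rec: EEGRecording) -> EEGRecording:
    """1 Hz high-pass then 45 Hz low-pass, both zero-phase FIR.

    Orders (1650 and 332 at 500 Hz) place the -6 dB points at 0.5 and
    47.5 Hz respectively.
    """
    hp = highpass_taps(rec.fs)
    if rec.n_samples < 3 * hp.size:
        raise PreprocessError(
            f"recording too short ({rec.n_samples} samples) for filter order "
            f"{hp.size - 1}")
    data = _fir_zero_phase(rec.data, hp)
    data = _fir_zero_phase(data, lowpass_taps(rec.fs))
    return replace(rec, data=data)


def trf_band_taps(fs: float, band=(1.0, 10.0), transition_hz: float = 0.5) -> np.ndarray:
    """1-10 Hz zero-phase FIR for TRF preparation (<=0.5 Hz transition)."""
    numtaps = int(round(3.3 * fs / transition_hz)) | 1
    return sps.firwin(numtaps, band, pass_zero=False, fs=fs)


# ---------------------------------------------------------------------------
# Bad-channel detection
# ---------------------------------------------------------------------------

def hurst_rs(x: np.ndarray, min_window: int = 16) -> float:
    """Hurst exponent by the rescaled-range (R/S) method.

    Mean R/S over non-overlapping windows at dyadic window sizes; the
    exponent is the slope of log(R/S) against log(window size).  White noise
    gives ~0.5, pink (1/f) noise close to 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    sizes = []
    w = min_window
    while w <= n // 4:
        sizes.append(w)
        w *= 2
    if len(sizes) < 2:
        raise ValueError("series too short for R/S estimate")
    log_rs = []
    for w in sizes:
        m = n // w
        seg = x[: m * w].reshape(m, w)
        seg = seg - seg.mean(axis=1, keepdims=True)
        cum = np.cumsum(seg, axis=1)
        rng = cum.max(axis=1) - cum.min(axis=1)
        std = seg.std(axis=1)
        ok = std > 0
        if not ok.any():
            log_rs.append(np.nan)
            continue
        log_rs.append(np.log(np.mean(rng[ok] / std[ok])))
    log_rs = np.asarray(log_rs)
    log_w = np.log(np.asarray(sizes, dtype=float))
    ok = np.isfinite(log_rs)
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(log_w[ok], log_rs[ok], 1)[0]
    return float(slope)


def _max_flat_run_s(x: np.ndarray, fs: float, eps: float = 1e-10) -> float:
    flat = np.abs(np.diff(x)) < eps
    if not flat.any():
        return 0.0
    # longest run of True
    changes = np.flatnonzero(np.diff(flat.astype(int)))
    bounds = np.concatenate(([-1], changes, [flat.size - 1]))
    best = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if flat[hi]:
            best = max(best, hi - lo)
    return (best + 1) / fs  # n flat diffs span n+1 samples


def detect_bad_channels(
    rec: EEGRecording,
    flat_s: float = 30.0,
    hurst_threshold: float = 0.7,
    power_sd: float = 2.75,
    power_band=(1.0, 100.0),
) -> set[str]:
    """Union of the flat, Hurst and log-power bad-channel rules."""
    if rec.duration_s < 60:
        raise PreprocessError("need at least 60 s of data for channel screening")
    if len(rec.channel_names) < 4:
        raise PreprocessError("need at least 4 channels to z-score power")
    bads: set[str] = set()
    log_powers = []
    for ci, name in enumerate(rec.channel_names):
        x = rec.data[:, ci]
        if _max_flat_run_s(x, rec.fs) > flat_s:
            bads.add(name)
        if hurst_rs(x) < hurst_threshold:
            bads.add(name)
        freqs, psd = sps.welch(x, fs=rec.fs, nperseg=int(min(rec.fs * 4, x.size)))
        hi = min(power_band[1], rec.fs / 2)
        sel = (freqs >= power_band[0]) & (freqs <= hi)
        log_powers.append(np.log(psd[sel].mean() + 1e-30))
    lp = np.asarray(log_powers)
    z = (lp - lp.mean()) / (lp.std() or 1.0)
    for ci, name in enumerate(rec.channel_names):
        if abs(z[ci]) > power_sd:
            bads.add(name)
    return bads


# ---------------------------------------------------------------------------
# Wavelet thresholding
# ---------------------------------------------------------------------------

def wavelet_threshold(
    rec: EEGRecording, level: int = 13, wavelet: str = "coif4"
) -> EEGRecording:
    """Remove large artifacts by per-level wavelet-coefficient clipping.

    Each channel is decomposed to ``level`` with an orthogonal wavelet
    (periodized).  Detail coefficients are clipped at the per-level
    universal threshold sigma*sqrt(2 ln n) with sigma from the median
    absolute deviation; clipping removes the super-threshold excess (the
    artifact) and leaves sub-threshold background EEG untouched.  The
    approximation coefficients are not altered.
    """
    if rec.n_samples < 2 ** level:
        raise PreprocessError(
            f"need at least 2^{level} samples for level-{level} decomposition")
    import warnings as _warnings

    out = np.empty_like(rec.data)
    for c in range(rec.data.shape[1]):
        x = rec.data[:, c]
        with _warnings.catch_warnings():
            # a fixed decomposition depth is part of the pipeline contract;
            # pywt warns when it exceeds the boundary-free maximum
            _warnings.simplefilter("ignore", UserWarning)
            coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
        new = [coeffs[0]]
        for d in coeffs[1:]:
            sigma = np.median(np.abs(d)) / 0.6745
            thr = sigma * np.sqrt(2 * np.log(max(d.size, 2)))
            new.append(np.clip(d, -thr, thr))
        out[:, c] = pywt.waverec(new, wavelet, mode="periodization")[: x.size]
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# Interpolation and re-referencing
# ---------------------------------------------------------------------------

def interpolate_channels(rec: EEGRecording, bads: set[str] | None = None) -> EEGRecording:
    """Replace bad channels with spherical-spline estimates (MNE backend)."""
    import mne

    bads = set(rec.bad_channels if bads is None else bads)
    if not bads:
        return replace(rec, bad_channels=set())
    if not bads <= set(rec.channel_names):
        raise ValueError("bads must be a subset of channel names")
    if rec.reference in bads:
        raise ValueError("cannot interpolate the reference channel")
    n_good = len(rec.channel_names) - len(bads)
    if len(bads) > len(rec.channel_names) / 2:
        raise PreprocessError("refusing to interpolate > 50% of channels")
    if n_good < 4:
        raise PreprocessError("need at least 4 good channels")
    info = mne.create_info(list(rec.channel_names), rec.fs, ch_types="eeg",
                           verbose="error")
    raw = mne.io.RawArray(rec.data.T * 1e-6, info, verbose="error")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for name in ("standard_1005", "spherical_1005"):
            try:
                montage = mne.channels.make_standard_montage(name)
                break
            except ValueError:
                continue
        raw.set_montage(montage, verbose="error")
    raw.info["bads"] = sorted(bads)
    raw.interpolate_bads(reset_bads=True, verbose="error")
    return replace(rec, data=raw.get_data().T * 1e6, bad_channels=set())


def rereference_mastoids(
    rec: EEGRecording, mastoids: tuple[str, str] = MASTOIDS
) -> EEGRecording:
    """Subtract the mean of the two mastoid channels from every channel."""
    for m in mastoids:
        if m not in rec.channel_names:
            raise ValueError(f"mastoid channel {m!r} not present")
    ref = 0.5 * (rec.channel(mastoids[0]) + rec.channel(mastoids[1]))
    return replace(rec, data=rec.data - ref[:, None],
                   reference="linked mastoids")


# ---------------------------------------------------------------------------
# Epoching / rejection / recombination
# ---------------------------------------------------------------------------

@dataclass
class EpochMask:
    """Keep/drop decision per consecutive 1 s epoch."""

    keep: np.ndarray
    epoch_length_s: float = 1.0
    threshold_uv: float = 200.0

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_dropped(self) -> int:
        return int((~self.keep).sum())


@dataclass
class RecombinedData:
    """TRF-ready EEG/predictor stream after epoch rejection.

    ``valid`` is False on the 1 s zero blocks inserted at discontinuities;
    those samples are deterministic zeros, not data, and are excluded from
    prediction-accuracy scoring downstream.
    """

    eeg: np.ndarray
    predictors: np.ndarray
    valid: np.ndarray
    fs: float
    mask: EpochMask
    retained_s: float


def epoch_mask(rec: EEGRecording, threshold_uv: float = 200.0,
               epoch_s: float = 1.0) -> EpochMask:
    """Flag 1 s epochs whose (unfiltered) amplitude exceeds the threshold."""
    ep_len = int(round(epoch_s * rec.fs))
    n_ep = rec.n_samples // ep_len
    keep = np.empty(n_ep, dtype=bool)
    for e in range(n_ep):
        seg = rec.data[e * ep_len:(e + 1) * ep_len]
        keep[e] = np.abs(seg).max() <= threshold_uv
    return EpochMask(keep=keep, epoch_length_s=epoch_s, threshold_uv=threshold_uv)


def epoch_reject_recombine(
    rec: EEGRecording,
    pred: PredictorSet,
    threshold_uv: float = 200.0,
    min_retained_s: float = 350.0,
    band=(1.0, 10.0),
) -> RecombinedData:
    """Filter 1-10 Hz, reject +/-200 uV epochs, recombine with 1 s zero gaps.

    The rejection decision is made on the unfiltered (pre-band-pass, post-
    cleaning) amplitudes and applied jointly to EEG and predictors.  Raises
    :class:`InsufficientDataError` when fewer than ``min_retained_s``
    seconds survive.
    """
    if pred.fs != rec.fs:
        raise ValueError("EEG and predictors must share a sampling rate")
    ep_len = int(round(rec.fs))
    mask = epoch_mask(rec, threshold_uv=threshold_uv)
    n_ep = mask.keep.size
    if pred.n_samples < n_ep * ep_len:
        raise ValueError("predictor stream shorter than the EEG epoch span")

    filt = _fir_zero_phase(rec.data, trf_band_taps(rec.fs, band=band))

    kept = np.flatnonzero(mask.keep)
    retained_s = kept.size * 1.0
    if retained_s < min_retained_s:
        raise InsufficientDataError(
            f"retained {retained_s:.0f} s < required {min_retained_s:.0f} s")

    eeg_parts, pred_parts, valid_parts = [], [], []
    zeros_e = np.zeros((ep_len, rec.data.shape[1]))
    zeros_p = np.zeros((ep_len, pred.data.shape[1]))
    prev = None
    for e in kept:
        if prev is not None and e != prev + 1:
            eeg_parts.append(zeros_e)
            pred_parts.append(zeros_p)
            valid_parts.append(np.zeros(ep_len, dtype=bool))
        sl = slice(e * ep_len, (e + 1) * ep_len)
        eeg_parts.append(filt[sl])
        pred_parts.append(pred.data[sl])
        valid_parts.append(np.ones(ep_len, dtype=bool))
        prev = e
    return RecombinedData(
        eeg=np.concatenate(eeg_parts) if eeg_parts else np.empty((0, rec.data.shape[1])),
        predictors=np.concatenate(pred_parts) if pred_parts else np.empty((0, pred.data.shape[1])),
        valid=np.concatenate(valid_parts) if valid_parts else np.empty(0, dtype=bool),
        fs=rec.fs,
        mask=mask,
        retained_s=retained_s,
    )
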