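"""EEG cleaning pipeline: filters, channel rules, wavelets, epoching."""

import numpy as np
import pytest
import scipy.signal as sps

from phonotrf import preprocess as pp
from phonotrf.predictors import PredictorSet
from phonotrf.synth import pink_noise

FS = 500.0


def _pink_channels(n_samples, n_channels, rng, scale=20.0):
    return np.column_stack(
        [scale * pink_noise(n_samples, rng) for _ in range(n_channels)])


class TestFilters:
    @pytest.mark.parametrize("taps_fn,freq,min_atten_db", [
        (pp.highpass_taps, 0.1, 20.0),
        (pp.lowpass_taps, 50.0, 20.0),
    ])
    def test_stopband_attenuation(self, taps_fn, freq, min_atten_db):
        _, h = sps.freqz(taps_fn(FS), worN=[freq], fs=FS)
        assert 20 * np.log10(abs(h[0])) < -min_atten_db

    @pytest.mark.parametrize("taps_fn", [pp.highpass_taps, pp.lowpass_taps])
    def test_passband_flat_at_10hz(self, taps_fn):
        _, h = sps.freqz(taps_fn(FS), worN=[10.0], fs=FS)
        assert abs(20 * np.log10(abs(h[0]))) < 1.0

    def test_minus6db_points(self):
        """The stated orders put the half-amplitude points at 0.5/47.5 Hz."""
        for taps_fn, f6 in ((pp.highpass_taps, 0.5), (pp.lowpass_taps, 47.5)):
            _, h = sps.freqz(taps_fn(FS), worN=[f6], fs=FS)
            assert 20 * np.log10(abs(h[0])) == pytest.approx(-6.0, abs=0.5)

    def test_zero_phase(self, rng):
        """A filtered passband burst is not delayed (noncausal filtering)."""
        n = int(FS * 60)
        t = np.arange(n) / FS
        env = np.exp(-0.5 * ((t - 30.0) / 0.5) ** 2)
        x = env * np.sin(2 * np.pi * 10 * t)
        rec = pp.EEGRecording(x[:, None], FS, ("ch0",))
        y = pp.bandpass_filters(rec).data[:, 0]
        xc = sps.correlate(y, x, mode="full")
        lag = np.argmax(np.abs(xc)) - (n - 1)
        assert abs(lag) <= 1

    def test_too_short_recording_rejected(self):
        rec = pp.EEGRecording(np.zeros((100, 1)), FS, ("ch0",))
        with pytest.raises(pp.PreprocessError):
            pp.bandpass_filters(rec)


class TestBadChannels:
    def test_three_rules_flag_their_fixtures_only(self, rng):
        n = int(FS * 90)
        n_ch = 16
        data = _pink_channels(n, n_ch, rng)
        names = tuple(f"ch{i}" for i in range(n_ch))
        data[:, 1] = 20 * rng.standard_normal(n)       # white: Hurst ~ 0.5
        data[: int(31 * FS), 2] = 3.14                 # flat for 31 s
        data[:, 3] *= 100.0                            # power outlier
        rec = pp.EEGRecording(data, FS, names)
        assert pp.detect_bad_channels(rec) == {"ch1", "ch2", "ch3"}

    def test_hurst_estimates(self, rng):
        white = rng.standard_normal(30000)
        pink = pink_noise(30000, rng)
        assert pp.hurst_rs(white) == pytest.approx(0.5, abs=0.1)
        assert pp.hurst_rs(pink) > 0.7

    def test_flat_run_below_threshold_not_flagged(self, rng):
        n = int(FS * 90)
        data = _pink_channels(n, 8, rng)
        data[: int(20 * FS), 0] = 1.0  # flat for only 20 s
        rec = pp.EEGRecording(data, FS, tuple(f"ch{i}" for i in range(8)))
        assert "ch0" not in pp.detect_bad_channels(rec)

    def test_preconditions(self, rng):
        short = pp.EEGRecording(_pink_channels(1000, 8, rng), FS,
                                tuple(f"ch{i}" for i in range(8)))
        with pytest.raises(pp.PreprocessError):
            pp.detect_bad_channels(short)
        few = pp.EEGRecording(_pink_channels(int(FS * 90), 3, rng), FS,
                              ("a", "b", "c"))
        with pytest.raises(pp.PreprocessError):
            pp.detect_bad_channels(few)


class TestWaveletThreshold:
    def test_zero_in_zero_out(self):
        rec = pp.EEGRecording(np.zeros((2 ** 13, 1)), FS, ("ch0",))
        assert not pp.wavelet_threshold(rec).data.any()

    def test_spike_removed_sinusoid_kept(self):
        n = 2 ** 14
        t = np.arange(n) / FS
        clean = 50 * np.sin(2 * np.pi * 5 * t)
        x = clean.copy()
        x[n // 2] += 500.0
        rec = pp.EEGRecording(x[:, None], FS, ("ch0",))
        out = pp.wavelet_threshold(rec).data[:, 0]
        assert abs(out[n // 2] - clean[n // 2]) <= 250.0
        assert np.corrcoef(out, clean)[0, 1] >= 0.95

    def test_variance_contracts(self, rng):
        x = 30 * pink_noise(2 ** 13, rng)
        rec = pp.EEGRecording(x[:, None], FS, ("ch0",))
        out = pp.wavelet_threshold(rec).data[:, 0]
        assert out.var() <= x.var() + 1e-12

    def test_too_short_rejected(self):
        rec = pp.EEGRecording(np.zeros((100, 1)), FS, ("ch0",))
        with pytest.raises(pp.PreprocessError):
            pp.wavelet_threshold(rec)


def _smooth_field_data(n, rng, scale=10.0):
    """Spatially smooth multichannel data (low-order functions of
    electrode position) for which spline interpolation is near-exact."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    P = np.array([pos[ch] for ch in pp.MONTAGE_28])
    basis = np.column_stack([P[:, 0], P[:, 1], P[:, 2],
                             P[:, 0] * P[:, 1], P[:, 0] ** 2,
                             np.ones(len(P))])
    return scale * rng.standard_normal((n, basis.shape[1])) @ basis.T


class TestInterpolation:
    def test_no_bads_is_identity(self, rng):
        data = _smooth_field_data(500, rng)
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        out = pp.interpolate_channels(rec, set())
        assert np.allclose(out.data, data)

    def test_leave_one_out_reconstruction(self, rng):
        data = _smooth_field_data(2000, rng)
        i = pp.MONTAGE_28.index("C3")
        truth = data[:, i].copy()
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        out = pp.interpolate_channels(rec, {"C3"})
        assert np.corrcoef(out.data[:, i], truth)[0, 1] >= 0.9

    def test_symmetric_data_symmetric_interpolation(self, rng):
        pairs = [("C3", "C4"), ("F3", "F4"), ("FC5", "FC6"), ("T7", "T8"),
                 ("CP5", "CP6"), ("P3", "P4"), ("F7", "F8"), ("Fp1", "Fp2"),
                 ("P7", "P8"), ("O1", "O2"), ("TP9", "TP10"), ("FC1", "FC2")]
        data = _smooth_field_data(1000, rng)
        for l, r in pairs:
            data[:, pp.MONTAGE_28.index(r)] = data[:, pp.MONTAGE_28.index(l)]
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        out = pp.interpolate_channels(rec, {"C3"})
        c3 = out.data[:, pp.MONTAGE_28.index("C3")]
        c4 = out.data[:, pp.MONTAGE_28.index("C4")]
        assert np.corrcoef(c3, c4)[0, 1] >= 0.99

    def test_refuses_majority_bad(self, rng):
        data = _smooth_field_data(500, rng)
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        bads = set(pp.MONTAGE_28[:13]) | {"C4", "T8"}  # 15 of 28, not Cz
        with pytest.raises(pp.PreprocessError):
            pp.interpolate_channels(rec, bads)


def test_read_raw_fif_round_trip(tmp_path, rng):
    """EEGRecording wraps MNE raw readers (uV scaling, channel names)."""
    import mne

    data_uv = 20 * rng.standard_normal((8, 1000))
    info = mne.create_info([f"ch{i}" for i in range(8)], 500.0,
                           ch_types="eeg", verbose="error")
    raw = mne.io.RawArray(data_uv * 1e-6, info, verbose="error")
    path = tmp_path / "test_raw.fif"
    raw.save(path, verbose="error")
    rec = pp.read_raw(path)
    assert rec.fs == 500.0
    assert rec.channel_names == tuple(f"ch{i}" for i in range(8))
    assert np.allclose(rec.data, data_uv.T, atol=1e-6)


class TestRereference:
    def test_zero_mastoids_identity(self, rng):
        data = rng.standard_normal((100, len(pp.MONTAGE_28)))
        for m in pp.MASTOIDS:
            data[:, pp.MONTAGE_28.index(m)] = 0.0
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        assert np.allclose(pp.rereference_mastoids(rec).data, data)

    def test_common_offset_removed(self):
        data = np.full((50, len(pp.MONTAGE_28)), 7.0)
        rec = pp.EEGRecording(data, FS, pp.MONTAGE_28)
        assert np.allclose(pp.rereference_mastoids(rec).data, 0.0)

    def test_constant_mastoids_shift(self):
        data = np.zeros((50, len(pp.MONTAGE_28)))
        data[:, pp.MONTAGE_28.index("TP9")] = 2.0
        data[:, pp.MONTAGE_28.index("TP10")] = 4.0
        out = pp.rereference_mastoids(
            pp.EEGRecording(data, FS, pp.MONTAGE_28))
        assert np.allclose(out.data[:, pp.MONTAGE_28.index("Fz")], -3.0)

    def test_missing_mastoid_errors(self):
        rec = pp.EEGRecording(np.zeros((10, 2)), FS, ("Fz", "Cz"))
        with pytest.raises(ValueError):
            pp.rereference_mastoids(rec)


class TestEpochRejectRecombine:
    fs = 100.0

    def _make(self, rng, n_s=400, spike_epochs=(), amp=250.0):
        n = int(self.fs * n_s)
        eeg = np.column_stack([20 * pink_noise(n, rng) for _ in range(2)])
        for e in spike_epochs:
            eeg[int(e * self.fs) + 5, 0] = amp
        pred = PredictorSet(
            (rng.random((n, 2)) < 0.5).astype(float), self.fs, ["a", "b"],
            "features")
        return pp.EEGRecording(eeg, self.fs, ("ch0", "ch1")), pred

    def test_clean_data_no_padding(self, rng):
        rec, pred = self._make(rng)
        res = pp.epoch_reject_recombine(rec, pred)
        assert res.mask.n_dropped == 0
        assert res.valid.all()
        assert res.eeg.shape[0] == res.mask.n_kept * int(self.fs)

    def test_spiked_epoch_dropped_with_zero_gap(self, rng):
        rec, pred = self._make(rng, spike_epochs=(50,))
        res = pp.epoch_reject_recombine(rec, pred)
        assert np.flatnonzero(~res.mask.keep).tolist() == [50]
        # one 1 s zero block bridges the discontinuity
        gap = ~res.valid
        assert gap.sum() == int(self.fs)
        assert not res.eeg[gap].any() and not res.predictors[gap].any()

    def test_epoch_count_conserved(self, rng):
        rec, pred = self._make(rng, spike_epochs=(10, 11, 300))
        res = pp.epoch_reject_recombine(rec, pred)
        assert res.mask.n_kept + res.mask.n_dropped == res.mask.keep.size

    def test_minimum_retained_enforced(self, rng):
        rec, pred = self._make(rng, n_s=349)
        with pytest.raises(pp.InsufficientDataError):
            pp.epoch_reject_recombine(rec, pred, min_retained_s=350.0)

    def test_deterministic(self, rng):
        rec, pred = self._make(rng, spike_epochs=(42,))
        a = pp.epoch_reject_recombine(rec, pred)
        b = pp.epoch_reject_recombine(rec, pred)
        assert np.array_equal(a.eeg, b.eeg)
        assert np.array_equal(a.valid, b.valid)
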