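"""Microphone equalization: difference spectra, filter design, timing neutrality."""

import numpy as np
import pytest
from scipy import signal

import batarray as ba
from batarray.calibration import filter_magnitude_db

FS = 375_000.0
BAND = (5_000.0, 140_000.0)


def _sweep_recording(fs=FS, dur=0.05, f_hi=140e3, f_lo=5e3, n_ch=1, pad=0.01):
    """Downward FM sweep like a calibration playback, padded with silence."""
    t = np.arange(int(dur * fs)) / fs
    x = signal.chirp(t, f_hi, dur, f_lo, method="logarithmic")
    x *= signal.windows.tukey(x.size, 0.05)
    x = np.r_[np.zeros(int(pad * fs)), x, np.zeros(int(pad * fs))]
    return ba.MultichannelRecording(samples=np.tile(x, (n_ch, 1)), sample_rate=fs)


class TestDifferenceSpectrum:
    def test_self_difference_is_zero(self):
        ref = _sweep_recording()
        f, d = ba.difference_spectrum(ref, ref, BAND)
        assert np.allclose(d, 0.0, atol=1e-9)
        assert f[0] >= BAND[0] and f[-1] <= BAND[1]

    def test_broadband_attenuation_recovered(self):
        ref = _sweep_recording()
        tgt = ba.MultichannelRecording(samples=ref.samples * 10 ** (-6 / 20),
                                       sample_rate=FS)
        _, d = ba.difference_spectrum(ref, tgt, BAND)
        np.testing.assert_allclose(d, 6.0, atol=0.01)

    def test_one_pole_lowpass_inverted(self):
        # target = reference through a known one-pole low-pass; the difference
        # must equal that filter's inverse magnitude (analytic oracle).
        fc = 40e3
        ref = _sweep_recording()
        b, a = signal.bilinear([1.0], [1.0 / (2 * np.pi * fc), 1.0], fs=FS)
        tgt = ba.MultichannelRecording(
            samples=signal.lfilter(b, a, ref.samples[0])[None, :], sample_rate=FS)
        f, d = ba.difference_spectrum(ref, tgt, (10e3, 120e3))
        _, h = signal.freqz(b, a, worN=f, fs=FS)
        oracle_db = -20 * np.log10(np.abs(h))
        assert np.max(np.abs(d - oracle_db)) < 1.0

    def test_sample_rate_mismatch_rejected(self):
        ref = _sweep_recording()
        tgt = ba.MultichannelRecording(samples=ref.samples, sample_rate=FS / 2)
        with pytest.raises(ValueError, match="mismatch"):
            ba.difference_spectrum(ref, tgt, BAND)

    def test_no_sweep_energy_rejected(self):
        silent = ba.MultichannelRecording(samples=np.zeros((1, 40960)),
                                          sample_rate=FS)
        with pytest.raises(ValueError, match="energy"):
            ba.difference_spectrum(silent, silent, BAND)


class TestSpectrumToFilter:
    def test_flat_zero_db_is_unit_impulse(self):
        f = np.linspace(5e3, 140e3, 100)
        flt = ba.spectrum_to_filter(f, np.zeros(100), FS, taps=255)
        h = flt.impulse_response
        gd = flt.group_delay_samples
        assert np.argmax(np.abs(h)) == gd
        assert h[gd] == pytest.approx(1.0, abs=1e-3)

    def test_flat_plus_6db_scales_output(self):
        f = np.linspace(5e3, 140e3, 100)
        flt = ba.spectrum_to_filter(f, np.full(100, 6.0), FS, taps=255)
        x = np.sin(2 * np.pi * 40e3 * np.arange(8192) / FS)
        from batarray._filters import apply_fir_zero_phase
        y = apply_fir_zero_phase(x, flt.impulse_response)
        gain = np.sqrt(np.mean(y[500:-500] ** 2) / np.mean(x[500:-500] ** 2))
        assert gain == pytest.approx(10 ** (6 / 20), rel=0.01)

    def test_tilt_matched_within_1db(self):
        # +6 dB/octave over 10-100 kHz; oracle = direct FFT of designed taps
        f = np.geomspace(10e3, 100e3, 200)
        tilt_db = 6.0 * np.log2(f / 10e3)
        flt = ba.spectrum_to_filter(f, tilt_db, FS, taps=511, max_gain_db=30.0)
        probe = np.geomspace(12e3, 90e3, 50)
        want = np.minimum(6.0 * np.log2(probe / 10e3), 30.0)
        nfft = 1 << 16
        mag = np.abs(np.fft.rfft(flt.impulse_response, nfft))
        grid = np.fft.rfftfreq(nfft, 1 / FS)
        got = 20 * np.log10(np.interp(probe, grid, mag))
        assert np.max(np.abs(got - want)) < 1.0

    def test_gain_cap_applied(self):
        f = np.linspace(5e3, 140e3, 50)
        flt = ba.spectrum_to_filter(f, np.full(50, 50.0), FS, taps=255,
                                    max_gain_db=30.0)
        assert np.max(flt.difference_db) == pytest.approx(30.0)

    def test_even_or_short_taps_rejected(self):
        f = np.linspace(5e3, 140e3, 10)
        with pytest.raises(ValueError):
            ba.spectrum_to_filter(f, np.zeros(10), FS, taps=256)
        with pytest.raises(ValueError):
            ba.spectrum_to_filter(f, np.zeros(10), FS, taps=21)


class TestApplyCalibration:
    def _filters(self, gains_db, taps=255):
        f = np.linspace(5e3, 140e3, 64)
        return [ba.spectrum_to_filter(f, np.full(64, g), FS, taps=taps)
                for g in gains_db]

    def test_identity_filters(self):
        rec = _sweep_recording(n_ch=2)
        out = ba.apply_calibration(rec, self._filters([0.0, 0.0]))
        err = np.max(np.abs(out.samples - rec.samples)) / np.max(np.abs(rec.samples))
        assert err < 1e-3

    def test_6db_filters_double_rms(self):
        rec = _sweep_recording(n_ch=1)
        out = ba.apply_calibration(rec, self._filters([6.0]))
        ratio = np.sqrt(np.mean(out.samples ** 2) / np.mean(rec.samples ** 2))
        assert ratio == pytest.approx(10 ** (6 / 20), rel=0.01)

    def test_count_mismatch(self):
        rec = _sweep_recording(n_ch=2)
        with pytest.raises(ValueError):
            ba.apply_calibration(rec, self._filters([0.0]))

    def test_tdoa_invariance_under_distinct_filters(self):
        # a common click delayed 100 samples between channels; per-channel
        # filters with different shapes must not move the correlation peak
        rng = np.random.default_rng(3)
        n = 16384
        click = signal.gausspulse(np.linspace(-1e-3, 1e-3, 751), fc=50e3)
        x0 = np.zeros(n); x0[4000:4751] += click
        x1 = np.zeros(n); x1[4100:4851] += click
        x0 += 1e-4 * rng.standard_normal(n)
        x1 += 1e-4 * rng.standard_normal(n)
        rec = ba.MultichannelRecording(samples=np.vstack([x0, x1]),
                                       sample_rate=FS)
        f = np.linspace(5e3, 140e3, 64)
        flts = [
            ba.spectrum_to_filter(f, np.zeros(64), FS, taps=255),
            ba.spectrum_to_filter(f, 4.0 * np.sin(f / 2e4), FS, taps=511),
        ]
        def peak_lag(a, b):
            r = signal.correlate(a, b, mode="full")
            return np.argmax(r) - (len(b) - 1)
        before = peak_lag(rec.samples[1], rec.samples[0])
        out = ba.apply_calibration(rec, flts)
        after = peak_lag(out.samples[1], out.samples[0])
        assert abs(after - before) <= 1

    def test_closed_loop_recovers_reference_spectrum(self):
        # filter built from (ref, target) applied to target reproduces the
        # reference's in-band spectrum within 1.5 dB
        ref = _sweep_recording()
        fc = 35e3
        b, a = signal.bilinear([1.0], [1.0 / (2 * np.pi * fc), 1.0], fs=FS)
        tgt = ba.MultichannelRecording(
            samples=signal.lfilter(b, a, ref.samples[0])[None, :], sample_rate=FS)
        flt = ba.build_calibration(ref, tgt, (10e3, 120e3), taps=1023)
        fixed = ba.apply_calibration(tgt, [flt])
        f, p_ref = signal.welch(ref.samples[0], fs=FS, nperseg=1024, detrend=False)
        _, p_fix = signal.welch(fixed.samples[0], fs=FS, nperseg=1024, detrend=False)
        sel = (f >= 12e3) & (f <= 110e3)
        err = 10 * np.log10(p_fix[sel] / p_ref[sel])
        assert np.max(np.abs(err)) < 1.5

    def test_filter_file_round_trip(self, tmp_path):
        from batarray.calibration import (load_calibration_filter,
                                          save_calibration_filter)
        f = np.linspace(5e3, 140e3, 64)
        flt = ba.spectrum_to_filter(f, 3.0 * np.cos(f / 3e4), FS, taps=255)
        save_calibration_filter(flt, tmp_path / "flt.csv")
        back = load_calibration_filter(tmp_path / "flt.csv", FS)
        np.testing.assert_allclose(back.impulse_response, flt.impulse_response,
                                   atol=1e-12)
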