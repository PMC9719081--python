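"""Averaged noise spectra and floor-referenced noise excess.

The recording system's self-noise ("noise floor") is measured with the
microphones acoustically blocked; external noise — e.g. from the UAV rotors
— is then quantified as the dB excess of its averaged spectrum over that
floor, per frequency bin.

Spectra are short-time power spectra (running FFT) averaged over all
windows: Hann window, default length 512 samples with 256-sample overlap.
Levels are band power per bin in dB re a reference pressure (20 µPa by
default), normalized so that the linear-power bins sum to the signal
variance (Parseval, with the window's noise-gain correction applied by the
underlying Welch estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_config import P_REF_PA, MultichannelRecording

__all__ = [
    "NoiseSpectrum",
    "running_fft_spectrum",
    "noise_excess",
    "record_noise_floor",
    "MIN_LEVEL_DB",
]

#: Clamp for zero-signal bins (avoids -inf propagation).
MIN_LEVEL_DB = -180.0


@dataclass
class NoiseSpectrum:
    """Averaged power spectrum: per-bin band power in dB re ``p_ref``."""

    frequency_hz: np.ndarray
    level_db: np.ndarray
    n_windows_averaged: int
    p_ref: float = P_REF_PA

    def __post_init__(self):
        if self.n_windows_averaged < 1:
            raise ValueError("need at least one averaged window")
        if not np.all(np.isfinite(self.level_db)):
            raise ValueError("levels must be finite")

    def linear_power(self) -> np.ndarray:
        """Per-bin band power in Pa^2 (inverse of the dB conversion)."""
        return self.p_ref ** 2 * 10.0 ** (self.level_db / 10.0)


def running_fft_spectrum(samples, sample_rate, window_length=512, overlap=256,
                         p_ref=P_REF_PA) -> NoiseSpectrum:
    """Running-FFT averaged power spectrum of one channel.

    Hann-windowed segments of ``window_length`` samples, advanced by
    ``window_length - overlap``, power-averaged over all windows.  Grid
    spacing is ``sample_rate / window_length``.  Bin values are band power
    (Pa^2 per bin) in dB re ``p_ref``; summing the linear bin powers
    recovers the signal variance (within the estimator's window correction).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("one channel at a time")
    if x.size < window_length:
        raise ValueError(
            f"input of {x.size} samples shorter than window ({window_length})")
    f, psd = signal.welch(
        x, fs=sample_rate, window="hann", nperseg=window_length,
        noverlap=overlap, detrend=False, scaling="density",
    )
    df = sample_rate / window_length
    band_power = psd * df  # Pa^2 per bin; sums to variance
    level = 10.0 * np.log10(np.maximum(band_power / p_ref ** 2, 1e-30))
    level = np.maximum(level, MIN_LEVEL_DB)
    hop = window_length - overlap
    n_win = 1 + (x.size - window_length) // hop
    return NoiseSpectrum(frequency_hz=f, level_db=level,
                         n_windows_averaged=n_win, p_ref=p_ref)


def noise_excess(spectrum: NoiseSpectrum, floor: NoiseSpectrum) -> np.ndarray:
    """Per-bin dB difference of a noise spectrum over the system floor.

    Negative values mean the measured noise is below the floor (i.e. the
    floor dominates).  Both spectra must share the same frequency grid.
    """
    if (spectrum.frequency_hz.shape != floor.frequency_hz.shape
            or not np.allclose(spectrum.frequency_hz, floor.frequency_hz)):
        raise ValueError("frequency grids differ")
    return spectrum.level_db - floor.level_db


def record_noise_floor(rec: MultichannelRecording, window_length=512,
                       overlap=256, p_ref=P_REF_PA):
    """Per-channel averaged floor spectra of a blocked-microphone recording.

    Returns a list with one :class:`NoiseSpectrum` per channel (index 0 =
    topmost microphone).  A silent channel is reported at the clamp level
    rather than −inf.
    """
    return [
        running_fft_spectrum(rec.samples[i], rec.sample_rate,
                             window_length=window_length, overlap=overlap,
                             p_ref=p_ref)
        for i in range(rec.channel_count)
    ]
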