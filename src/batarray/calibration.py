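"""Substitution-method microphone calibration.

Field microphones (small electrets) are equalized against a flat laboratory
reference microphone by playing the same frequency-modulated sweep to both,
computing the reference-minus-target difference spectrum, and converting that
difference into a linear-phase correction filter applied to all subsequent
recordings.  Because every correction filter is linear phase with its group
delay removed on application, calibration is timing-neutral: inter-channel
time differences of arrival are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from ._filters import apply_fir_zero_phase, design_fir_from_magnitude, fir_magnitude_db
from .io_config import MultichannelRecording

logger = logging.getLogger("batarray")

__all__ = [
    "CalibrationFilter",
    "difference_spectrum",
    "spectrum_to_filter",
    "apply_calibration",
]


@dataclass
class CalibrationFilter:
    """Per-microphone correction: difference spectrum and its FIR realization."""

    frequency_hz: np.ndarray
    difference_db: np.ndarray
    impulse_response: np.ndarray
    valid_band: tuple

    @property
    def group_delay_samples(self) -> int:
        return (len(self.impulse_response) - 1) // 2


def difference_spectrum(reference, target, band, nperseg=1024,
                        min_snr_db=-60.0):
    """Reference-minus-target magnitude difference spectrum in dB.

    Both single-channel recordings must contain the same played sweep at the
    same sample rate.  Spectra are estimated by Welch-averaged periodograms
    (grid spacing ``fs / nperseg`` <= 500 Hz at typical ultrasonic rates) and
    the difference is restricted to ``band``.

    Returns ``(frequency_hz, diff_db)``.
    """
    ref = np.asarray(reference.samples[0] if isinstance(reference, MultichannelRecording)
                     else reference, dtype=float)
    tgt = np.asarray(target.samples[0] if isinstance(target, MultichannelRecording)
                     else target, dtype=float)
    fs_ref = reference.sample_rate if isinstance(reference, MultichannelRecording) else None
    fs_tgt = target.sample_rate if isinstance(target, MultichannelRecording) else None
    if fs_ref is None or fs_tgt is None:
        raise TypeError("difference_spectrum expects MultichannelRecording inputs")
    if fs_ref != fs_tgt:
        raise ValueError(f"sample-rate mismatch: {fs_ref} vs {fs_tgt}")
    fs = fs_ref

    f, p_ref = signal.welch(ref, fs=fs, nperseg=nperseg, detrend=False)
    _, p_tgt = signal.welch(tgt, fs=fs, nperseg=nperseg, detrend=False)

    lo, hi = band
    sel = (f >= lo) & (f <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} contains no spectral bins")
    # sweep-energy check: in-band level must rise above an (empty-band) floor
    total = np.sum(p_ref)
    if total <= 0 or 10 * np.log10(np.sum(p_ref[sel]) / total + 1e-30) < min_snr_db:
        raise ValueError("no detectable sweep energy in the requested band")

    diff_db = 10.0 * np.log10(np.maximum(p_ref[sel], 1e-30)
                              / np.maximum(p_tgt[sel], 1e-30))
    return f[sel], diff_db


def spectrum_to_filter(frequency_hz, diff_db, sample_rate, taps=511,
                       max_gain_db=30.0) -> CalibrationFilter:
    """Realize a difference spectrum as a linear-phase correction FIR.

    Gains above ``max_gain_db`` are capped (with a warning): unbounded
    inversion of a microphone's roll-off amplifies out-of-band noise.
    Outside the valid band the response holds the band-edge value.
    """
    frequency_hz = np.asarray(frequency_hz, dtype=float)
    diff_db = np.asarray(diff_db, dtype=float)
    if taps < 31 or taps % 2 == 0:
        raise ValueError("taps must be an odd integer >= 31")
    if not np.all(np.isfinite(diff_db)):
        raise ValueError("difference spectrum contains non-finite values")
    if np.any(diff_db > max_gain_db):
        logger.warning("spectrum_to_filter: gain capped at %+.0f dB", max_gain_db)
        diff_db = np.minimum(diff_db, max_gain_db)
    h = design_fir_from_magnitude(frequency_hz, diff_db, sample_rate, taps)
    return CalibrationFilter(
        frequency_hz=frequency_hz,
        difference_db=diff_db,
        impulse_response=h,
        valid_band=(float(frequency_hz[0]), float(frequency_hz[-1])),
    )


def build_calibration(reference, target, band, taps=511, max_gain_db=30.0):
    """Convenience: difference spectrum -> correction filter in one step."""
    f, d = difference_spectrum(reference, target, band)
    flt = spectrum_to_filter(f, d, reference.sample_rate, taps=taps,
                             max_gain_db=max_gain_db)
    return flt


def apply_calibration(rec: MultichannelRecording, filters) -> MultichannelRecording:
    """Apply one correction filter per channel, preserving timing.

    Each channel is convolved with its filter and the filter's group delay is
    removed, so TDOAs between channels are unchanged (within one sample) even
    when channels carry different filters.
    """
    if len(filters) != rec.channel_count:
        raise ValueError(
            f"{len(filters)} filters for {rec.channel_count} channels")
    out = np.empty_like(rec.samples)
    for i, flt in enumerate(filters):
        out[i] = apply_fir_zero_phase(rec.samples[i], flt.impulse_response)
    return MultichannelRecording(samples=out, sample_rate=rec.sample_rate,
                                 start_time=rec.start_time)


def filter_magnitude_db(flt: CalibrationFilter, sample_rate, freq_hz):
    """Measured magnitude of the realized FIR (for verification plots/tests)."""
    return fir_magnitude_db(flt.impulse_response, sample_rate, freq_hz)


def save_calibration_filter(flt: CalibrationFilter, path):
    """Persist a filter as a two-column (frequency_hz, difference_db) table.

    The tap count rides in the header comment; the impulse response is
    re-derived deterministically on load.
    """
    header = f"taps={len(flt.impulse_response)}\nfrequency_hz difference_db"
    np.savetxt(path, np.column_stack([flt.frequency_hz, flt.difference_db]),
               header=header)


def load_calibration_filter(path, sample_rate, max_gain_db=30.0) -> CalibrationFilter:
    """Rebuild a filter saved by :func:`save_calibration_filter`."""
    taps = 511
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "taps=" in line:
                taps = int(line.split("taps=")[1].strip())
                break
    data = np.loadtxt(path)
    return spectrum_to_filter(data[:, 0], data[:, 1], sample_rate, taps=taps,
                              max_gain_db=max_gain_db)
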