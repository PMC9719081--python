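"""Linear-phase FIR design from a target magnitude response.

Shared by the calibration (microphone equalization) and propagation
(absorption compensation) modules.  Filters are designed by frequency
sampling with a raised-cosine (Hann) window, so they are exactly linear
phase with group delay (taps - 1) / 2 samples; callers remove the group
delay to keep inter-channel timing untouched.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def design_fir_from_magnitude(freq_hz, gain_db, sample_rate, taps):
    """Design a linear-phase FIR matching ``gain_db`` at ``freq_hz``.

    Outside the span of ``freq_hz`` the gain is held at the nearest band-edge
    value (no extrapolated boost).  ``taps`` must be odd (type-I FIR).
    """
    freq_hz = np.asarray(freq_hz, dtype=float)
    gain_db = np.asarray(gain_db, dtype=float)
    if taps % 2 == 0:
        raise ValueError("taps must be odd for a type-I linear-phase FIR")
    if freq_hz.ndim != 1 or freq_hz.size < 2 or np.any(np.diff(freq_hz) <= 0):
        raise ValueError("freq_hz must be strictly increasing with >= 2 points")
    nyq = sample_rate / 2.0

    # dense design grid, edges held constant
    grid = np.linspace(0.0, nyq, 2049)
    g_db = np.interp(grid, freq_hz, gain_db,
                     left=gain_db[0], right=gain_db[-1])
    gain_lin = 10.0 ** (g_db / 20.0)
    h = signal.firwin2(taps, grid / nyq, gain_lin, window="hann")
    return h


def fir_magnitude_db(taps_arr, sample_rate, freq_hz):
    """Measured magnitude response of an FIR in dB at given frequencies."""
    w, h = signal.freqz(taps_arr, worN=np.asarray(freq_hz, dtype=float),
                        fs=sample_rate)
    mag = np.abs(h)
    return 20.0 * np.log10(np.maximum(mag, 1e-12))


def apply_fir_zero_phase(x, taps_arr):
    """Convolve with a linear-phase FIR and remove its group delay.

    Output has the same length and timing as the input, so time differences
    between channels filtered with different (odd-length) FIRs are preserved.
    """
    x = np.asarray(x, dtype=float)
    gd = (len(taps_arr) - 1) // 2
    full = signal.fftconvolve(x, taps_arr, mode="full")
    return full[gd:gd + len(x)]
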