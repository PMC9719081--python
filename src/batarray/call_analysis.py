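"""Echolocation call detection and parameterization.

Calls are detected on a band-limited magnitude envelope, segmented on all
channels over a common time window, and parameterized the way bat
bioacousticians report them:

* **duration** and **RMS pressure** are taken over the call's 95%-energy
  window — the span holding the central 95% of cumulative squared pressure
  (symmetric 2.5%/97.5% trim), robust to onset/offset ambiguity;
* **peak frequency** is the spectral maximum over that window;
* **minimum frequency** is the lowest frequency still within a fixed
  threshold (default 15 dB) of the peak, searched downward from the peak;
* **pulse interval** is the start-to-start spacing of consecutive
  95%-energy windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_config import MultichannelRecording

logger = logging.getLogger("batarray")

__all__ = [
    "CallSegment",
    "CallMeasurement",
    "detect_calls",
    "energy_window_95",
    "rms_pressure",
    "call_spectrum_features",
    "pulse_intervals",
    "analyze_recording",
    "extract_segments",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CallSegment:
    """One detected call on one channel.

    ``samples`` holds the band-limited pressure series of the analysis
    window, which is the detection bounds padded on both sides;
    ``window_start_s`` is the absolute time of ``samples[0]``.
    """

    channel: int
    start_s: float
    end_s: float
    samples: np.ndarray
    sample_rate: float
    window_start_s: float
    band_hz: tuple = (15000.0, 100000.0)
    e95_start_s: float | None = None
    e95_end_s: float | None = None

    @property
    def duration_ms(self) -> float:
        if self.e95_start_s is None:
            raise ValueError("95%-energy window not set")
        return (self.e95_end_s - self.e95_start_s) * 1e3

    def e95_slice(self) -> np.ndarray:
        if self.e95_start_s is None:
            raise ValueError("95%-energy window not set")
        i0 = int(round((self.e95_start_s - self.window_start_s) * self.sample_rate))
        i1 = int(round((self.e95_end_s - self.window_start_s) * self.sample_rate))
        return self.samples[i0:i1 + 1]


@dataclass
class CallMeasurement:
    """Per-call parameters; times on the recording axis (reference channel)."""

    call_id: int
    time_s: float                 # midpoint of the 95% window, reference channel
    duration_ms: float
    peak_frequency_khz: float
    min_frequency_khz: float
    rms_pressure_pa: np.ndarray   # per channel (NaN where call below threshold)
    reference_channel: int
    start_s: float                # detection bounds (all channels)
    end_s: float
    e95_start_s: float            # reference channel
    pulse_interval_ms: float | None = None


# ---------------------------------------------------------------------------
# Envelope + detection
# ---------------------------------------------------------------------------

def _band_sos(band, fs):
    lo, hi = band
    nyq = fs / 2
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} invalid for sample rate {fs}")
    return signal.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def _envelope(x, fs, band, lp_cutoff_hz=2000.0):
    """Magnitude envelope: band-limit, rectify, low-pass at 2 kHz."""
    xb = signal.sosfiltfilt(_band_sos(band, fs), x)
    sos_lp = signal.butter(2, lp_cutoff_hz / (fs / 2), btype="low", output="sos")
    env = signal.sosfiltfilt(sos_lp, np.abs(xb))
    return xb, np.maximum(env, 0.0)


def _runs_above(mask):
    """(start, stop) index pairs of contiguous True runs; stop exclusive."""
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts, stops))


def detect_calls(samples, sample_rate, noise_floor_estimate=None,
                 threshold_db=12.0, min_duration_ms=2.0, merge_gap_ms=5.0,
                 band=(15000.0, 100000.0), pad_fraction=0.2,
                 channel=0) -> list:
    """Detect calls on one channel; returns time-ordered :class:`CallSegment`.

    The detection statistic is the rectified, 2-kHz-low-passed envelope of the
    band-limited signal.  A call is a run where the envelope exceeds
    ``floor + threshold_db`` for at least ``min_duration_ms``; runs closer
    than ``merge_gap_ms`` are merged.  ``noise_floor_estimate`` is the
    envelope's noise level in pascals (median of the envelope when omitted).
    An empty list is a valid result.
    """
    x = np.asarray(samples, dtype=float)
    fs = sample_rate
    min_len = int(round(min_duration_ms * 1e-3 * fs))
    if x.size <= min_len:
        raise ValueError("signal shorter than the minimum call duration")
    xb, env = _envelope(x, fs, band)
    floor = float(np.median(env)) if noise_floor_estimate is None \
        else float(noise_floor_estimate)
    thresh = max(floor, 1e-12) * 10.0 ** (threshold_db / 20.0)
    mask = env > thresh
    if not mask.any():
        return []

    runs = _runs_above(mask)
    # merge runs separated by less than merge_gap
    gap = int(round(merge_gap_ms * 1e-3 * fs))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    segs = []
    for s, e in merged:
        if e - s < min_len:
            continue
        pad = int(round(pad_fraction * (e - s)))
        w0, w1 = max(0, s - pad), min(x.size, e + pad)
        seg = CallSegment(
            channel=channel, start_s=s / fs, end_s=e / fs,
            samples=xb[w0:w1].copy(), sample_rate=fs,
            window_start_s=w0 / fs, band_hz=tuple(band),
        )
        energy_window_95(seg)
        segs.append(seg)
    return segs


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def energy_window_95(seg: CallSegment):
    """Locate the central 95% of cumulative energy (2.5% -> 97.5% trim).

    Sets ``e95_start_s``/``e95_end_s`` on the segment and returns them.  The
    window is inclusive on both ends; for an isolated impulse it collapses to
    a single sample.
    """
    x = np.asarray(seg.samples, dtype=float)
    e = x * x
    total = e.sum()
    if total <= 0:
        raise ValueError("zero-energy segment")
    cum = np.cumsum(e)
    i0 = int(np.searchsorted(cum, 0.025 * total))
    i1 = int(np.searchsorted(cum, 0.975 * total))
    i1 = min(i1, x.size - 1)
    seg.e95_start_s = seg.window_start_s + i0 / seg.sample_rate
    seg.e95_end_s = seg.window_start_s + i1 / seg.sample_rate
    return seg.e95_start_s, seg.e95_end_s


def rms_pressure(seg: CallSegment) -> float:
    """RMS sound pressure (Pa) within the 95%-energy window."""
    w = seg.e95_slice()
    if w.size == 0:
        raise ValueError("empty 95% window")
    return float(np.sqrt(np.mean(w ** 2)))


def call_spectrum_features(seg: CallSegment, edge_threshold_db=15.0,
                           smooth_hz=500.0, min_fft=512):
    """Peak and minimum frequency (kHz) from the 95%-window spectrum.

    The power spectrum of the 95%-energy window (zero-padded to at least
    ``min_fft`` points when shorter, with a warning) is smoothed over
    ``smooth_hz`` to tame sweep ripple.  Peak frequency is the spectral
    maximum inside the segment's analysis band; minimum frequency is found by
    descending from the peak toward 0 Hz until the spectrum drops more than
    ``edge_threshold_db`` below the peak.
    """
    w = seg.e95_slice()
    fs = seg.sample_rate
    n = w.size
    if n < min_fft:
        logger.warning("call window of %d samples zero-padded to %d", n, min_fft)
    nfft = max(min_fft, n)
    spec = np.abs(np.fft.rfft(w, nfft)) ** 2
    freq = np.fft.rfftfreq(nfft, 1 / fs)

    k = max(1, int(round(smooth_hz / (fs / nfft))))
    if k > 1:
        kernel = np.ones(k) / k
        spec = np.convolve(spec, kernel, mode="same")

    lo, hi = seg.band_hz
    in_band = (freq >= lo) & (freq <= hi)
    if not in_band.any():
        raise ValueError("analysis band outside spectrum")
    band_idx = np.flatnonzero(in_band)
    ipk = band_idx[int(np.argmax(spec[band_idx]))]
    peak_khz = freq[ipk] / 1e3

    thresh = spec[ipk] * 10.0 ** (-edge_threshold_db / 10.0)
    imin = ipk
    while imin > 0 and spec[imin - 1] >= thresh:
        imin -= 1
    min_khz = freq[imin] / 1e3
    return peak_khz, min_khz


def pulse_intervals(measurements):
    """Fill start-to-start pulse intervals (ms) on a time-ordered call list.

    Intervals use the 95%-window start times on each call's reference
    channel; the first call carries no interval.
    """
    starts = [m.e95_start_s for m in measurements]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("measurements must be sorted by time")
    for prev, cur in zip(measurements, measurements[1:]):
        cur.pulse_interval_ms = (cur.e95_start_s - prev.e95_start_s) * 1e3
    if measurements:
        measurements[0].pulse_interval_ms = None
    return measurements


# ---------------------------------------------------------------------------
# Multichannel analysis
# ---------------------------------------------------------------------------

def extract_segments(rec: MultichannelRecording, start_s, end_s,
                     band=(15000.0, 100000.0), pad_fraction=0.2):
    """Band-limited per-channel segments over a common absolute window.

    Used to re-segment a recording from tabulated detection bounds (pipeline
    stages exchange bounds through CSV).  Returns one :class:`CallSegment`
    per channel with the 95% window computed where the energy is nonzero.
    """
    fs = rec.sample_rate
    pad = pad_fraction * (end_s - start_s)
    w0 = max(0, int(round((start_s - pad - rec.start_time) * fs)))
    w1 = min(rec.n_samples, int(round((end_s + pad - rec.start_time) * fs)))
    if w1 <= w0:
        raise ValueError("empty extraction window")
    sos = _band_sos(band, fs)
    segs = []
    for ch in range(rec.channel_count):
        xb = signal.sosfiltfilt(sos, rec.samples[ch, w0:w1])
        seg = CallSegment(
            channel=ch, start_s=start_s, end_s=end_s, samples=xb,
            sample_rate=fs, window_start_s=rec.start_time + w0 / fs,
            band_hz=tuple(band),
        )
        energy_window_95(seg)
        segs.append(seg)
    return segs


def analyze_recording(rec: MultichannelRecording, band=(15000.0, 100000.0),
                      threshold_db=12.0, min_duration_ms=2.0, merge_gap_ms=5.0,
                      pad_fraction=0.2, edge_threshold_db=15.0,
                      max_tdoa_s=0.015):
    """Detect and parameterize calls across all channels.

    Detection runs on the floor-normalized envelope maximum across channels,
    so a call is found whenever it is visible on any microphone and the
    detection bounds cover its earliest to latest arrival (the inter-channel
    spread is at most the array's end-to-end travel time).  Each call is then
    segmented per channel over a common window padded by ``max_tdoa_s``; the
    reference channel is the one with the highest call RMS (best SNR).

    Returns ``(measurements, segments_per_call)`` where ``segments_per_call``
    is a list (one entry per call) of per-channel :class:`CallSegment` lists.
    """
    fs = rec.sample_rate
    n_ch = rec.channel_count

    env_norm = None
    for ch in range(n_ch):
        _, env = _envelope(rec.samples[ch], fs, band)
        floor = max(float(np.median(env)), 1e-12)
        e = env / floor
        env_norm = e if env_norm is None else np.maximum(env_norm, e)

    thresh = 10.0 ** (threshold_db / 20.0)
    mask = env_norm > thresh
    measurements, segments_per_call = [], []
    if not mask.any():
        return measurements, segments_per_call

    runs = _runs_above(mask)
    gap = int(round(merge_gap_ms * 1e-3 * fs))
    min_len = int(round(min_duration_ms * 1e-3 * fs))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    call_id = 0
    for s, e in merged:
        if e - s < min_len:
            continue
        start_s = rec.start_time + s / fs
        end_s = rec.start_time + e / fs
        segs = extract_segments(rec, start_s - max_tdoa_s, end_s + max_tdoa_s,
                                band=band, pad_fraction=pad_fraction)
        rms = np.array([rms_pressure(sg) for sg in segs])
        ref = int(np.argmax(rms))
        ref_seg = segs[ref]
        peak_khz, min_khz = call_spectrum_features(
            ref_seg, edge_threshold_db=edge_threshold_db)
        m = CallMeasurement(
            call_id=call_id,
            time_s=0.5 * (ref_seg.e95_start_s + ref_seg.e95_end_s),
            duration_ms=ref_seg.duration_ms,
            peak_frequency_khz=peak_khz,
            min_frequency_khz=min_khz,
            rms_pressure_pa=rms,
            reference_channel=ref,
            start_s=start_s, end_s=end_s,
            e95_start_s=ref_seg.e95_start_s,
        )
        measurements.append(m)
        segments_per_call.append(segs)
        call_id += 1

    pulse_intervals(measurements)
    return measurements, segments_per_call
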