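"""TDOA localization of calls on a collinear microphone array.

A sound from position (r, z) — perpendicular range r from the array axis,
axial coordinate z re the array midpoint — reaches microphone i at distance
``d_i = sqrt(r^2 + (z - m_i)^2)``.  Time differences of arrival (TDOAs)
against a reference microphone constrain (r, z) on intersecting hyperbolae;
with at least two independent delays the position is recovered by nonlinear
least squares.  The collinear geometry is rotationally ambiguous about the
axis, so estimates live in the half-plane r >= 0.

TDOAs are measured by cross-correlation of band-limited call segments with
parabolic sub-sample peak interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .io_config import ArrayGeometry, EnvironmentConditions

logger = logging.getLogger("batarray")

__all__ = [
    "TdoaSet",
    "SourceEstimate",
    "sound_speed",
    "estimate_tdoa",
    "localize",
    "assemble_flightpath",
]


def sound_speed(env: EnvironmentConditions, humidity_correction=False) -> float:
    """Speed of sound in air, m/s: ``c = 331.3 · sqrt(1 + T/273.15)``.

    With ``humidity_correction`` a first-order moist-air term ``(1 + 0.16 x_w)``
    is applied, where ``x_w`` is the water-vapour molar fraction (adds about
    +0.6 m/s at 20 °C, 50 % RH); off by default since the dry formula is
    already within the accuracy of field temperature measurements.
    """
    c = 331.3 * np.sqrt(1.0 + env.temperature_c / 273.15)
    if humidity_correction:
        T = env.temperature_c + 273.15
        psat_kpa = 101.325 * 10.0 ** (-6.8346 * (273.16 / T) ** 1.261 + 4.6151)
        x_w = env.relative_humidity_pct / 100.0 * psat_kpa / env.pressure_kpa
        c *= 1.0 + 0.16 * x_w
    return float(c)


@dataclass
class TdoaSet:
    """Measured delays of each usable channel relative to the reference."""

    reference_channel: int
    channels: np.ndarray          # non-reference channel indices with usable delays
    delays_s: np.ndarray          # arrival(channel) - arrival(reference), seconds
    peak_correlation: np.ndarray  # normalized cross-correlation peak, [0, 1]


@dataclass
class SourceEstimate:
    """Localized call in the (r, z) half-plane."""

    call_id: int
    r_m: float
    z_m: float
    emission_time_s: float
    residual_rms_s: float
    distances_m: np.ndarray
    converged: bool = True
    ambiguous: bool = False
    in_range: bool = True


# ---------------------------------------------------------------------------
# TDOA estimation
# ---------------------------------------------------------------------------

def _xcorr_delay(x, y, fs, max_lag_s):
    """Delay of x relative to y (positive = x later) with sub-sample precision.

    Standard cross-correlation restricted to physically possible lags, with
    parabolic interpolation around the integer peak.  Returns
    ``(delay_s, normalized_peak)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = signal.correlate(x, y, mode="full", method="fft")
    lags = np.arange(-(y.size - 1), x.size)
    max_lag = int(np.ceil(max_lag_s * fs))
    sel = np.abs(lags) <= max_lag
    r_sel = r[sel]
    lags_sel = lags[sel]
    i = int(np.argmax(r_sel))
    norm = np.sqrt(np.sum(x * x) * np.sum(y * y))
    rho = float(r_sel[i] / norm) if norm > 0 else 0.0

    # parabolic sub-sample interpolation around the peak
    frac = 0.0
    if 0 < i < r_sel.size - 1:
        ym1, y0, yp1 = r_sel[i - 1], r_sel[i], r_sel[i + 1]
        denom = ym1 - 2 * y0 + yp1
        if denom < 0:
            frac = 0.5 * (ym1 - yp1) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
    return (lags_sel[i] + frac) / fs, rho


def estimate_tdoa(segments, reference_channel=None, geometry=None, c=343.0,
                  min_correlation=0.2, guard_s=5e-4) -> TdoaSet:
    """Per-channel delays of a call relative to the reference channel.

    ``segments`` is one band-filtered :class:`~batarray.call_analysis.CallSegment`
    per channel, all covering the same absolute window.  Pairs whose
    normalized correlation peak falls below ``min_correlation`` are dropped;
    delays beyond the array's end-to-end travel time (plus a guard) are
    physically impossible and are likewise dropped.
    """
    n = len(segments)
    if n < 3:
        raise ValueError("need segments on at least three channels")
    fs = segments[0].sample_rate
    if reference_channel is None:
        energies = [float(np.sum(np.square(s.samples))) for s in segments]
        reference_channel = int(np.argmax(energies))
    ref = segments[reference_channel].samples
    if geometry is not None:
        max_lag_s = geometry.max_tdoa_s(c) + guard_s
    else:
        max_lag_s = (segments[0].samples.size - 1) / fs

    chans, delays, rhos = [], [], []
    for i, seg in enumerate(segments):
        if i == reference_channel:
            continue
        if seg.samples.size != ref.size:
            raise ValueError("segments must share a common window")
        d, rho = _xcorr_delay(seg.samples, ref, fs, max_lag_s)
        if rho < min_correlation:
            logger.debug("channel %d dropped: correlation %.2f below %.2f",
                         i, rho, min_correlation)
            continue
        chans.append(i)
        delays.append(d)
        rhos.append(rho)
    return TdoaSet(
        reference_channel=reference_channel,
        channels=np.array(chans, dtype=int),
        delays_s=np.array(delays, dtype=float),
        peak_correlation=np.array(rhos, dtype=float),
    )


# ---------------------------------------------------------------------------
# Position solving
# ---------------------------------------------------------------------------

def _model_delays(r, z, mics, m_ref, c):
    d = np.sqrt(r * r + (z - mics) ** 2)
    d_ref = np.sqrt(r * r + (z - m_ref) ** 2)
    return (d - d_ref) / c, d_ref


def _algebraic_init(u, mics, m_ref):
    """Closed-form start: the squared-distance equations are linear in
    (d_ref, z) for a collinear array: u_i·d_ref + (m_i − m_ref)·z =
    (m_i² − m_ref² − u_i²)/2 with u_i = c·τ_i."""
    A = np.column_stack([u, mics - m_ref])
    b = 0.5 * (mics ** 2 - m_ref ** 2 - u ** 2)
    try:
        (d_ref, z), *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if not np.isfinite(d_ref) or d_ref <= 0:
        return None
    r_sq = d_ref ** 2 - (z - m_ref) ** 2
    r = np.sqrt(max(r_sq, 1e-6))
    return float(r), float(z)


_GRID_R = (1.0, 3.0, 5.0, 10.0, 20.0)
_GRID_Z = (-10.0, -5.0, 0.0, 5.0, 10.0)


def localize(tdoas: TdoaSet, geometry: ArrayGeometry, c: float,
             call_id=0, arrival_time_s=0.0, max_range_m=30.0) -> SourceEstimate:
    """Solve for (r, z) minimizing the squared TDOA misfit.

    Starts from the closed-form algebraic solution and refines by bounded
    nonlinear least squares (r >= 0); a 5x5 (r, z) multi-start grid is the
    fallback when the algebraic start does not converge to a good fit.  When
    two starts reach distinct minima with residuals within 1 %, the
    smaller-r solution is preferred and the estimate is flagged ambiguous.

    The emission time is the reference-channel arrival time minus the
    modelled reference travel time ``d_ref / c``.
    """
    if geometry.n_mics < 3:
        raise ValueError("localization needs at least three microphones")
    if tdoas.delays_s.size < 2:
        raise ValueError("localization needs at least two usable delays")
    mics = geometry.mic_axis_positions[tdoas.channels]
    m_ref = geometry.mic_axis_positions[tdoas.reference_channel]
    tau = tdoas.delays_s

    def residuals(p):
        model, _ = _model_delays(p[0], p[1], mics, m_ref, c)
        return model - tau

    def refine(start):
        try:
            res = optimize.least_squares(
                residuals, np.asarray(start, float),
                bounds=([0.0, -np.inf], [np.inf, np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except ValueError:
            return None
        if not res.success:
            return None
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
        return float(res.x[0]), float(res.x[1]), rms

    solutions = []
    init = _algebraic_init(c * tau, mics, m_ref)
    if init is not None:
        sol = refine(init)
        if sol is not None:
            solutions.append(sol)

    # accept a near-exact algebraic fit without the grid sweep
    good = solutions and solutions[0][2] < 0.02 * max(np.max(np.abs(tau)), 1e-6)
    if not good:
        for r0 in _GRID_R:
            for z0 in _GRID_Z:
                sol = refine((r0, z0))
                if sol is not None:
                    solutions.append(sol)

    if not solutions:
        logger.warning("call %s: no solver start converged", call_id)
        return SourceEstimate(call_id=call_id, r_m=np.nan, z_m=np.nan,
                              emission_time_s=np.nan, residual_rms_s=np.nan,
                              distances_m=np.full(geometry.n_mics, np.nan),
                              converged=False)

    best_rms = min(s[2] for s in solutions)
    # distinct minima within 1% residual of the best -> prefer smaller r, flag
    close = [s for s in solutions
             if s[2] <= best_rms * 1.01 + 1e-15]
    close.sort(key=lambda s: s[0])
    r, z, rms = close[0]
    distinct = any(abs(s[0] - r) > 0.05 * max(r, 1.0) or
                   abs(s[1] - z) > 0.05 * max(abs(z), 1.0) for s in close[1:])

    d_all = np.sqrt(r ** 2 + (z - geometry.mic_axis_positions) ** 2)
    d_ref = d_all[tdoas.reference_channel]
    est = SourceEstimate(
        call_id=call_id, r_m=r, z_m=z,
        emission_time_s=arrival_time_s - d_ref / c,
        residual_rms_s=rms, distances_m=d_all,
        converged=True, ambiguous=distinct,
        in_range=bool(np.hypot(r, z) <= max_range_m),
    )
    if not est.in_range:
        logger.info("call %s localized beyond %g m: low confidence",
                    call_id, max_range_m)
    return est


def assemble_flightpath(estimates, gap_s=1.0) -> pd.DataFrame:
    """Link time-ordered localized calls into flightpaths.

    Consecutive calls join the same path unless their emission times are more
    than ``gap_s`` apart.  Returns a table with a ``path_id`` column and a
    finite-difference ``speed_m_s`` estimate within each path (NaN on the
    first call of a path).
    """
    rows = [{"call_id": e.call_id, "time_s": e.emission_time_s,
             "r_m": e.r_m, "z_m": e.z_m}
            for e in estimates if e.converged]
    df = pd.DataFrame(rows, columns=["call_id", "time_s", "r_m", "z_m"])
    if df.empty:
        df["path_id"] = pd.Series(dtype=int)
        df["speed_m_s"] = pd.Series(dtype=float)
        return df
    dt = df["time_s"].diff()
    df["path_id"] = (dt > gap_s).cumsum().astype(int)
    ds = np.hypot(df["r_m"].diff(), df["z_m"].diff())
    speed = ds / dt
    speed[df["path_id"].diff() != 0] = np.nan
    df["speed_m_s"] = speed
    return df
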