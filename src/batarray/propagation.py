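"""Atmospheric transmission loss and source-level estimation.

Sound travelling from a bat to a microphone loses energy to spherical
spreading (20·log10 of the distance ratio) and to frequency-dependent
atmospheric absorption, which rises steeply through the ultrasonic band and
depends on temperature, humidity and static pressure.  This module models
absorption with the standard humid-air closed form (classical losses plus
O2 and N2 vibrational relaxation), builds linear-phase compensation filters
that restore the absorbed spectrum, and converts compensated received
pressures into source levels referenced to 0.1 m.

Source level convention: dB RMS re 20 µPa at 0.1 m, with the RMS taken over
the call's 95%-energy window; energy level adds 10·log10(duration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._filters import apply_fir_zero_phase, design_fir_from_magnitude
from .io_config import P_REF_PA, EnvironmentConditions

logger = logging.getLogger("batarray")

__all__ = [
    "REFERENCE_DISTANCE_M",
    "AbsorptionModel",
    "SourceLevelResult",
    "absorption_coefficient",
    "attenuation_filter",
    "compensate_transmission_loss",
    "source_level",
]

#: Reference distance for source levels (bat bioacoustics convention), metres.
REFERENCE_DISTANCE_M = 0.1


def absorption_coefficient(f, env: EnvironmentConditions):
    """Atmospheric absorption coefficient alpha(f) in dB/m.

    Full humid-air closed form: classical (viscous/thermal) attenuation plus
    the O2 and N2 vibrational relaxation terms, each governed by a humidity-
    and pressure-dependent relaxation frequency.  Valid for 0 < f <= 1 MHz.

    Parameters
    ----------
    f : float or ndarray
        Frequency in Hz.
    env : EnvironmentConditions
        Temperature, relative humidity and static pressure.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1e6):
        raise ValueError("frequency must be in (0, 1e6] Hz")

    T = env.temperature_c + 273.15
    T0 = 293.15           # reference temperature, K
    T01 = 273.16          # triple point of water, K
    p_rel = env.pressure_kpa / 101.325

    # molar concentration of water vapour (percent)
    psat_rel = 10.0 ** (-6.8346 * (T01 / T) ** 1.261 + 4.6151)
    h = env.relative_humidity_pct * psat_rel / p_rel

    # relaxation frequencies of oxygen and nitrogen, Hz
    f_rO = p_rel * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    f_rN = (p_rel / np.sqrt(T / T0)
            * (9.0 + 280.0 * h * np.exp(-4.170 * ((T / T0) ** (-1 / 3) - 1.0))))

    alpha = 8.686 * f ** 2 * (
        1.84e-11 / p_rel * np.sqrt(T / T0)
        + (T / T0) ** (-5 / 2) * (
            0.01275 * np.exp(-2239.1 / T) / (f_rO + f ** 2 / f_rO)
            + 0.1068 * np.exp(-3352.0 / T) / (f_rN + f ** 2 / f_rN)
        )
    )
    return alpha


@dataclass
class AbsorptionModel:
    """Callable wrapper binding an environment to alpha(f) in dB/m."""

    env: EnvironmentConditions

    def alpha_db_per_m(self, f):
        return absorption_coefficient(f, self.env)

    def __call__(self, f):
        return self.alpha_db_per_m(f)


def attenuation_filter(distance_m, env, sample_rate, taps=257,
                       max_boost_db=40.0, f_min_hz=1000.0):
    """Linear-phase FIR that undoes absorption over a propagation path.

    Magnitude is ``10^(alpha(f)·(d − d_ref)/20)`` — a rising gain that
    restores the energy absorbed between the 0.1-m reference distance and the
    microphone — capped at ``max_boost_db`` so compensation at long range and
    high frequency cannot amplify the noise floor without bound.

    Returns
    -------
    taps_arr : ndarray
        Odd-length FIR; group delay ``(taps − 1) // 2`` samples (removed by
        :func:`~batarray._filters.apply_fir_zero_phase`).
    """
    if distance_m < REFERENCE_DISTANCE_M:
        raise ValueError(
            f"distance {distance_m} m below reference {REFERENCE_DISTANCE_M} m")
    nyq = sample_rate / 2.0
    freq = np.linspace(f_min_hz, min(nyq, 1e6) * 0.999, 513)
    boost_db = absorption_coefficient(freq, env) * (distance_m - REFERENCE_DISTANCE_M)
    if np.any(boost_db > max_boost_db):
        f_cap = freq[boost_db > max_boost_db]
        logger.warning(
            "attenuation_filter: boost capped at %+.0f dB above %.1f kHz "
            "(d = %.1f m)", max_boost_db, f_cap[0] / 1e3, distance_m)
        boost_db = np.minimum(boost_db, max_boost_db)
    return design_fir_from_magnitude(freq, boost_db, sample_rate, taps)


def compensate_transmission_loss(samples, distance_m, env, sample_rate,
                                 absorption=True, max_boost_db=40.0, taps=257):
    """Refer a received pressure series back to the 0.1-m reference distance.

    The segment is filtered with the absorption-compensation FIR (group delay
    removed) and multiplied by ``d / 0.1`` to undo spherical spreading
    (+20·log10(d/0.1) dB).  With ``absorption=False`` only spreading is
    undone — useful as an analytic sanity case.
    """
    samples = np.asarray(samples, dtype=float)
    if distance_m <= REFERENCE_DISTANCE_M:
        if distance_m == REFERENCE_DISTANCE_M:
            return samples.copy()
        raise ValueError("distance must exceed the 0.1-m reference distance")
    out = samples
    if absorption:
        h = attenuation_filter(distance_m, env, sample_rate, taps=taps,
                               max_boost_db=max_boost_db)
        out = apply_fir_zero_phase(out, h)
    return out * (distance_m / REFERENCE_DISTANCE_M)


@dataclass
class SourceLevelResult:
    """Source level of one call on one channel, re 20 µPa at 0.1 m."""

    call_id: int
    channel: int
    distance_m: float
    sl_db_rms: float
    energy_db: float
    duration_ms: float


def source_level(rms_pressure_pa, duration_s, call_id=0, channel=0,
                 distance_m=np.nan) -> SourceLevelResult:
    """Convert a compensated RMS pressure into a source level.

    ``sl_db_rms = 20·log10(rms / 20 µPa)``; the energy level integrates the
    RMS level over the 95%-window duration:
    ``energy_db = sl_db_rms + 10·log10(duration_s)``.
    """
    if rms_pressure_pa <= 0:
        raise ValueError("RMS pressure must be positive")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    sl = 20.0 * np.log10(rms_pressure_pa / P_REF_PA)
    energy = sl + 10.0 * np.log10(duration_s)
    return SourceLevelResult(
        call_id=call_id, channel=channel, distance_m=float(distance_m),
        sl_db_rms=float(sl), energy_db=float(energy),
        duration_ms=float(duration_s * 1e3),
    )
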