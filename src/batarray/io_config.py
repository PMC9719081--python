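"""Recordings, array geometry, environment and configuration I/O.

The package works in physical units throughout: sample amplitudes are sound
pressures in pascals, microphone positions are metres along the (vertical)
array axis, and times are seconds from the start of the recording.  WAV files
carry no absolute-pressure convention, so the pascals-per-full-scale factor of
each channel is declared in the configuration file, not embedded in the audio.

Channel order convention: index 0 is the **topmost** microphone; axis
coordinates are metres relative to the array midpoint, positive upwards.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

logger = logging.getLogger("batarray")

__all__ = [
    "MultichannelRecording",
    "ArrayGeometry",
    "EnvironmentConditions",
    "Config",
    "ConfigError",
    "read_recording",
    "write_recording",
    "load_config",
    "save_config",
    "default_geometry",
]

#: Reference pressure for all dB sound-pressure levels (20 µPa, airborne sound).
P_REF_PA = 20e-6


class ConfigError(ValueError):
    """Raised when a configuration file is missing or has invalid fields."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultichannelRecording:
    """Synchronized multichannel pressure time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Per-channel sound pressure in pascals.
    sample_rate : float
        Sampling rate in Hz (identical for all channels).
    start_time : float, optional
        Time of the first sample on the recording time axis, seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels, samples) array")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.channel_count < 1:
            raise ValueError("at least one channel required")

    @property
    def channel_count(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds on the recording time axis."""
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class ArrayGeometry:
    """Collinear microphone array along a vertical axis.

    ``mic_axis_positions`` are metres along the axis, ordered top (index 0) to
    bottom, relative to the array midpoint (positive up).  The collinear
    layout makes localization rotationally ambiguous about the axis, so source
    positions live in the half-plane (perpendicular range r >= 0, axial
    coordinate z).
    """

    mic_axis_positions: np.ndarray
    axis_orientation: str = "vertical"

    def __post_init__(self) -> None:
        pos = np.asarray(self.mic_axis_positions, dtype=np.float64)
        if pos.ndim != 1 or pos.size < 2:
            raise ValueError("need at least two microphone positions")
        d = np.diff(pos)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("microphone positions must be strictly monotone")
        # normalize to top-to-bottom (descending z, index 0 = topmost)
        if d[0] > 0:
            pos = pos[::-1]
        self.mic_axis_positions = pos

    @property
    def n_mics(self) -> int:
        return self.mic_axis_positions.size

    @property
    def span_m(self) -> float:
        return float(self.mic_axis_positions[0] - self.mic_axis_positions[-1])

    def max_tdoa_s(self, c: float) -> float:
        """Largest physically possible arrival-time difference, seconds."""
        return self.span_m / c


def default_geometry() -> ArrayGeometry:
    """Four microphones spaced 1.30 m on a 4-m boom (span 3.90 m)."""
    z = np.array([1.95, 0.65, -0.65, -1.95])
    return ArrayGeometry(mic_axis_positions=z)


@dataclass
class EnvironmentConditions:
    """Atmospheric state used for sound speed and absorption.

    temperature_c in [-20, 50] °C, relative_humidity_pct in [0, 100],
    pressure_kpa > 0 (static pressure).
    """

    temperature_c: float = 15.0
    relative_humidity_pct: float = 70.0
    pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        errs = []
        if not -20.0 <= self.temperature_c <= 50.0:
            errs.append(f"temperature_c={self.temperature_c} outside [-20, 50]")
        if not 0.0 <= self.relative_humidity_pct <= 100.0:
            errs.append(
                f"relative_humidity_pct={self.relative_humidity_pct} outside [0, 100]"
            )
        if self.pressure_kpa <= 0:
            errs.append(f"pressure_kpa={self.pressure_kpa} must be > 0")
        if errs:
            raise ConfigError("; ".join(errs))


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_recording(path, calibration_scale=1.0) -> MultichannelRecording:
    """Read a multichannel WAV file and scale samples to pascals.

    Parameters
    ----------
    path : str or Path
        WAV file (PCM-16, PCM-32 or float-32).
    calibration_scale : float or sequence of float
        Pascals per full-scale amplitude, scalar or one value per channel.

    Returns
    -------
    MultichannelRecording
        Samples in pascals, shape (n_channels, n_samples).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    n_channels = data.shape[1]

    scale = np.atleast_1d(np.asarray(calibration_scale, dtype=np.float64))
    if scale.size == 1:
        scale = np.full(n_channels, scale[0])
    if scale.size != n_channels:
        raise ValueError(
            f"calibration_scale has {scale.size} entries but file has "
            f"{n_channels} channels"
        )

    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")

    samples = (x * scale[None, :]).T
    return MultichannelRecording(samples=samples, sample_rate=float(rate))


def write_recording(rec, path, bit_depth=32, calibration_scale=1.0):
    """Write a recording to WAV, mapping pascals back to full scale.

    ``bit_depth`` 32 writes IEEE float-32 (the default, quantization-free for
    simulated fixtures); 16 writes PCM-16.  Samples whose scaled amplitude
    exceeds full scale are clipped; the clip count is logged and returned.
    """
    rec_samples = np.asarray(rec.samples, dtype=np.float64)
    if not np.all(np.isfinite(rec_samples)):
        raise ValueError("samples contain non-finite values")
    n_channels = rec_samples.shape[0]
    scale = np.atleast_1d(np.asarray(calibration_scale, dtype=np.float64))
    if scale.size == 1:
        scale = np.full(n_channels, scale[0])
    if scale.size != n_channels:
        raise ValueError("calibration_scale count does not match channel count")

    x = (rec_samples / scale[:, None]).T  # (n_samples, n_channels) full-scale units
    n_clipped = int(np.count_nonzero(np.abs(x) > 1.0))
    if n_clipped:
        logger.warning("write_recording: clipped %d samples exceeding full scale",
                       n_clipped)
        x = np.clip(x, -1.0, 1.0)

    if bit_depth == 32:
        wavfile.write(str(path), int(round(rec.sample_rate)), x.astype(np.float32))
    elif bit_depth == 16:
        q = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), int(round(rec.sample_rate)), q)
    else:
        raise ValueError(f"unsupported bit depth {bit_depth} (use 16 or 32)")
    return n_clipped


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_DETECTION = {
    "band_hz": [15000.0, 100000.0],
    "threshold_db": 12.0,
    "min_duration_ms": 2.0,
    "merge_gap_ms": 5.0,
    "segment_pad_fraction": 0.2,
    "edge_threshold_db": 15.0,
}

DEFAULT_LOCALIZATION = {
    "max_range_m": 30.0,
    "min_correlation": 0.2,
    "path_gap_s": 1.0,
}

DEFAULT_SIMULATOR = {
    "sample_rate_hz": 375000.0,
    "noise_floor_db": 40.0,
}


@dataclass
class Config:
    """Validated pipeline configuration: geometry, environment and parameters."""

    geometry: ArrayGeometry
    environment: EnvironmentConditions
    detection: dict = field(default_factory=lambda: dict(DEFAULT_DETECTION))
    localization: dict = field(default_factory=lambda: dict(DEFAULT_LOCALIZATION))
    simulator: dict = field(default_factory=lambda: dict(DEFAULT_SIMULATOR))
    calibration_scale: float | list = 1.0


def _merge_defaults(section: dict, defaults: dict, name: str) -> dict:
    out = dict(defaults)
    for k, v in section.items():
        if k not in defaults:
            raise ConfigError(f"unknown key '{k}' in section '{name}'")
        out[k] = v
    for k in defaults:
        if k not in section:
            logger.debug("config: %s.%s defaulted to %r", name, k, defaults[k])
    return out


def load_config(path) -> Config:
    """Parse a YAML configuration file into a validated :class:`Config`.

    Missing optional sections fall back to documented defaults (the default
    geometry is the 4-microphone, 1.30-m-spacing boom).  Invalid fields are
    reported individually.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> Config:
    errs = []

    geo_raw = raw.get("geometry")
    if geo_raw is None:
        geometry = default_geometry()
        logger.debug("config: geometry defaulted to 4 mics spaced 1.30 m")
    else:
        try:
            if "mic_positions_m" in geo_raw:
                pos = np.asarray(geo_raw["mic_positions_m"], dtype=float)
            else:
                n = int(geo_raw.get("n_mics", 4))
                spacing = float(geo_raw.get("spacing_m", 1.30))
                span = spacing * (n - 1)
                pos = span / 2 - spacing * np.arange(n)
            geometry = ArrayGeometry(mic_axis_positions=pos)
        except (ValueError, TypeError) as e:
            errs.append(f"geometry: {e}")
            geometry = default_geometry()

    env_raw = raw.get("environment", {}) or {}
    try:
        environment = EnvironmentConditions(
            temperature_c=float(env_raw.get("temperature_c", 15.0)),
            relative_humidity_pct=float(env_raw.get("relative_humidity_pct", 70.0)),
            pressure_kpa=float(env_raw.get("pressure_kpa", 101.325)),
        )
    except ConfigError as e:
        errs.append(f"environment: {e}")
        environment = None

    try:
        detection = _merge_defaults(raw.get("detection", {}) or {},
                                    DEFAULT_DETECTION, "detection")
    except ConfigError as e:
        errs.append(str(e))
        detection = dict(DEFAULT_DETECTION)
    try:
        localization = _merge_defaults(raw.get("localization", {}) or {},
                                       DEFAULT_LOCALIZATION, "localization")
    except ConfigError as e:
        errs.append(str(e))
        localization = dict(DEFAULT_LOCALIZATION)
    try:
        simulator = _merge_defaults(raw.get("simulator", {}) or {},
                                    DEFAULT_SIMULATOR, "simulator")
    except ConfigError as e:
        errs.append(str(e))
        simulator = dict(DEFAULT_SIMULATOR)

    if errs:
        raise ConfigError("; ".join(errs))

    return Config(
        geometry=geometry,
        environment=environment,
        detection=detection,
        localization=localization,
        simulator=simulator,
        calibration_scale=raw.get("calibration_scale", 1.0),
    )


def save_config(cfg: Config, path) -> None:
    """Serialize a :class:`Config` to YAML (round-trips through load_config)."""
    out = {
        "geometry": {
            "mic_positions_m": [float(p) for p in cfg.geometry.mic_axis_positions]
        },
        "environment": {
            "temperature_c": cfg.environment.temperature_c,
            "relative_humidity_pct": cfg.environment.relative_humidity_pct,
            "pressure_kpa": cfg.environment.pressure_kpa,
        },
        "detection": cfg.detection,
        "localization": cfg.localization,
        "simulator": cfg.simulator,
        "calibration_scale": cfg.calibration_scale,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
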