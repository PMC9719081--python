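import numpy as np
import pytest

import batarray as ba

FS = 375_000.0


@pytest.fixture
def env20():
    """Reference lab atmosphere: 20 degC, 50 % RH, standard pressure."""
    return ba.EnvironmentConditions(temperature_c=20.0,
                                    relative_humidity_pct=50.0,
                                    pressure_kpa=101.325)


@pytest.fixture
def geometry():
    return ba.default_geometry()


@pytest.fixture
def cfg():
    return ba.Config(geometry=ba.default_geometry(),
                     environment=ba.EnvironmentConditions())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_segment(x, fs=FS, band=(15e3, 100e3)):
    """Wrap a raw waveform as an analyzed CallSegment (95% window set)."""
    seg = ba.CallSegment(channel=0, start_s=0.0, end_s=len(x) / fs,
                         samples=np.asarray(x, float), sample_rate=fs,
                         window_start_s=0.0, band_hz=band)
    ba.energy_window_95(seg)
    return seg


@pytest.fixture(scope="session")
def short_flyby():
    """Small simulated pass (8 m -> 2 m -> 8 m) shared across tests."""
    scn = ba.serotine_flyby_scenario(seed=7, snr_db=30.0, start_range_m=8.0,
                                     closest_r_m=2.0, speed_m_s=5.0)
    rec, truth = ba.simulate_flyby(scn)
    return scn, rec, truth
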