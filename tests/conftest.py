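import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from soniquant.emissions import BandScheme, BurstSpectrum, NoiseFloor


@pytest.fixture(scope="session")
def scheme():
    return BandScheme()


@pytest.fixture()
def flat_floor():
    """Noise floor with all bands at -60 dB, SD 1 dB."""
    bands = ("subharmonic", "harmonic2", "harmonic3", "broadband")
    return NoiseFloor(
        mean_db={b: -60.0 for b in bands},
        sd_db={b: 1.0 for b in bands},
        source="early_burst",
        n_samples=30,
    )


def make_burst(sub=-60.0, h2=-60.0, h3=-60.0, bb=-60.0, **kw) -> BurstSpectrum:
    return BurstSpectrum(
        band_power_db={"subharmonic": sub, "harmonic2": h2, "harmonic3": h3, "broadband": bb},
        **kw,
    )


@pytest.fixture()
def burst_factory():
    return make_burst
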