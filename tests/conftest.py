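import numpy as np
import pytest

from aeropath.simulate import SimulationConfig, default_array, generate_dataset
from aeropath.telemetry import Detection, DetectionSeries

#: Printed station coordinates used across the geometry tests.
KENT = (44.5833, -66.75)          # 44 deg 35' N, 66 deg 45' W
IDH = (44.6, -67.266667)          # 44 deg 36' N, 67 deg 16' W
PETIT_MANAN = (44.4, -67.9)       # 44 deg 24' N, 67 deg 54' W

#: Reduced level set used by the integration fixtures (a declared subset).
TEST_LEVELS = ("10m", "30m", "1000mb", "975mb", "950mb", "925mb", "900mb")


def make_series(times, strengths=None, tag="T001", station="S", antenna=0):
    strengths = strengths if strengths is not None else [50.0] * len(times)
    dets = [
        Detection(tag, station, antenna, float(t), float(s))
        for t, s in zip(times, strengths)
    ]
    return DetectionSeries(tag, station, dets)


@pytest.fixture(scope="session")
def stations():
    return default_array()

@pytest.fixture(scope="session")
def idh_station(stations):
    return next(s for s in stations if s.name == "InnerDoubleHeadshotIs")


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded end-to-end synthetic dataset on the reduced level set."""
    return generate_dataset(SimulationConfig(seed=1, levels=TEST_LEVELS))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
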