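import numpy as np
import pytest

from fluoroacc import CArmGeometry


@pytest.fixture
def ap_geometry():
    return CArmGeometry(sid_mm=1200.0, sod_mm=800.0, label="AP")


@pytest.fixture
def lao60_geometry():
    return CArmGeometry(sid_mm=1200.0, sod_mm=800.0, primary_deg=60.0, label="LAO60")


@pytest.fixture
def rng():
    return np.random.default_rng(20231104)


def random_geometry(rng) -> CArmGeometry:
    sod = rng.uniform(600.0, 900.0)
    return CArmGeometry(
        sid_mm=sod * rng.uniform(1.2, 2.0),
        sod_mm=sod,
        primary_deg=rng.uniform(-90.0, 90.0),
        secondary_deg=rng.uniform(-45.0, 45.0),
    )
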