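import numpy as np
import pytest

from irproc import fixtures
from irproc.radiometry import (
    AcquisitionParams,
    AtmosphereModel,
    CalibrationConstants,
)

# Constants of a typical consumer long-wave camera, used for scalar-level
# tests (no storage constraint, so the offset can be negative as stored by
# real cameras).
CAL = CalibrationConstants(G=21106.77, O=-7261.0, B=1501.0, R=0.012545, F=1.0)
ATM = AtmosphereModel(alpha1=0.006569, alpha2=0.01262, beta1=-0.002276, beta2=-0.00667, X=1.9)
PARAMS = AcquisitionParams(
    emissivity=0.95, air_temp_C=20.0, rel_humidity=0.5, app_refl_temp_C=20.0, distance_m=1.0
)


@pytest.fixture
def cal():
    return CAL


@pytest.fixture
def atm():
    return ATM


@pytest.fixture
def params():
    return PARAMS


def make_scene(**kw) -> fixtures.SceneSpec:
    """SceneSpec with small defaults suitable for fast tests."""
    kw.setdefault("width", 48)
    kw.setdefault("height", 32)
    return fixtures.SceneSpec(**kw)


@pytest.fixture
def two_region_spec():
    """Scene with a 40 degC rectangle on a 20 degC background."""
    return make_scene(
        background_C=20.0,
        objects=[fixtures.SceneObject("rectangle", 8, 8, 16, 12, temperature_C=40.0)],
    )


@pytest.fixture
def fixture_folder(tmp_path, two_region_spec):
    """Folder with three radiometric JPEG fixtures at different temperatures."""
    rng = np.random.default_rng(7)
    for i, bg in enumerate((15.0, 22.0, 30.0)):
        spec = make_scene(
            background_C=bg,
            objects=[
                fixtures.SceneObject("disk", 24, 16, 8, 0, temperature_C=bg + 10.0)
            ],
            noise_sd_dn=2.0,
            seed=int(rng.integers(2**31)),
        )
        raw = fixtures.render_scene(spec)
        fixtures.package_fixture(raw, spec, tmp_path, f"img{i}", kind="jpeg")
    return tmp_path
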