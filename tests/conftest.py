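import numpy as np
import pytest

from focalspect import collimators as cg
from focalspect import phantoms as phf


@pytest.fixture(scope="session")
def tiny_liver():
    """Small liver phantom + 8-view orbit for operator-level tests."""
    bundle = phf.make_liver_phantom((32, 32, 24), 7.0, tumor_radius_mm=10.0)
    orbit = phf.plan_orbit(bundle, 8, 1.0)
    return bundle, orbit


@pytest.fixture(scope="session")
def single_view_orbit():
    """Two opposed views at a fixed 300 mm radius, centered at origin."""
    return cg.DetectorOrbit(angles_deg=[0.0, 180.0],
                            radii_mm=[300.0, 300.0],
                            time_per_view_s=1.0,
                            center_mm=np.zeros(3))


@pytest.fixture(scope="session")
def all_collimators():
    return {
        "parallel": cg.make_collimator("parallel"),
        "conebeam50": cg.make_collimator("conebeam", 50.0),
        "conebeam100": cg.make_collimator("conebeam", 100.0),
        "multifocal": cg.make_collimator("multifocal", 50.0),
    }
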