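import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from kesct.materials import default_registry
    return default_registry()


@pytest.fixture(scope="session")
def spectrum_pair():
    """Default calibrated unfiltered spectrum and its 290 um iodine-filtered
    counterpart."""
    from kesct.spectrum import default_spectrum_pair
    return default_spectrum_pair()


@pytest.fixture(scope="session")
def desk_phantom():
    from kesct.phantom import KidneyPhantomConfig, kidney_phantom
    return kidney_phantom(KidneyPhantomConfig(grid_size=256,
                                              voxel_size_mm=0.14))


def make_geometry(n: int, voxel_mm: float, angles_deg) -> "object":
    """Geometry whose effective pixel matches the phantom voxel exactly."""
    from kesct.forward import Geometry
    return Geometry(angles_deg=np.asarray(angles_deg, dtype=float),
                    n_detector_bins=n,
                    detector_pixel_um=voxel_mm * 1000.0 * 16.4 / 15.3)


@pytest.fixture()
def geometry_factory():
    return make_geometry
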