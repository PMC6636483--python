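import numpy as np
import pytest
from hypothesis import settings

from cartmorph.presets import GeometrySettings, default_config
from cartmorph.profiles import build_profile

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return default_config(master_seed=0)


@pytest.fixture(scope="session")
def geometry():
    return GeometrySettings()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_profile(geometry):
    """A lesion-free, fibrillation-free 200 um section on the condylar arc."""
    return build_profile(200.0, 0.0, geometry, np.random.default_rng(0))


@pytest.fixture(scope="session")
def study():
    """One default simulated study, shared across read-only tests."""
    from cartmorph.synthetic import simulate_study

    return simulate_study(default_config(master_seed=0), seed=0)


def flat_profile(thickness=200.0, roi=(-3500.0, 3500.0), flank=1000.0, spacing=5.0,
                 surface_y=None):
    """Hand-built flat band: surface at y=thickness, tidemark at y=0."""
    from cartmorph.profiles import CartilageProfile

    lo, hi = roi[0] - flank, roi[1] + flank
    x = np.arange(lo, hi + spacing, spacing)
    y_s = np.full_like(x, thickness) if surface_y is None else surface_y(x)
    profile = CartilageProfile(
        surface=np.column_stack([x, y_s]),
        tidemark=np.column_stack([x, np.zeros_like(x)]),
        roi=roi,
        flanks=((lo, roi[0]), (roi[1], hi)),
    )
    profile.validate(roi_width=roi[1] - roi[0])
    return profile
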