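import numpy as np
import pytest

from dose4d import GridGeometry, RunConfig, VoxelGrid
from dose4d.phantom import PhantomSpec, build_phantom


def small_phantom_spec(**overrides) -> PhantomSpec:
    """Compact thorax phantom for unit tests (2 mm CT grid, 4 mm dose grid)."""
    kwargs = dict(
        ct_shape=(48, 48, 32), ct_spacing=(2.0, 2.0, 2.0),
        dose_shape=(24, 24, 16), dose_spacing=(4.0, 4.0, 4.0),
        body_radii=(44.0, 44.0, 30.0), lung_radii=(36.0, 32.0, 28.0),
        tumor_radii=(6.0, 6.0, 6.0),
        cord_center=(0.0, 38.0), airway_center=(0.0, -20.0),
        amp_si=8.0, amp_ap=2.0, falloff_mm=14.0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def small_run_config(**overrides) -> RunConfig:
    kwargs = dict(
        phantom=small_phantom_spec(),
        mtv_margins_mm=(1.0,), include_itv=False, include_midv=False,
        bixel_size=(5.0, 5.0), n_bixels=(10, 10),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phases():
    return build_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def static_phases():
    """Zero-motion variant: all phases identical, all DVFs zero."""
    return build_phantom(small_phantom_spec(amp_si=0.0, amp_ap=0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)) -> VoxelGrid:
    geom = GridGeometry.centered(shape, spacing)
    return VoxelGrid(rng.uniform(0.0, 1.0, geom.shape), geom.spacing, geom.origin)
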