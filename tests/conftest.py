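import numpy as np
import pytest

from octaflow.containers import ScanPattern
from octaflow.phantom import Disk, PhantomSpec, SpeckleModel, VesselLayer
from octaflow.studies import (
    mini_layers,
    mini_patterns,
    mini_phantom,
    mini_roi,
)


@pytest.fixture(scope="session")
def patterns():
    return mini_patterns()


@pytest.fixture(scope="session")
def phantom():
    return mini_phantom(seed=11)


@pytest.fixture(scope="session")
def layers():
    return mini_layers()


@pytest.fixture(scope="session")
def roi():
    return mini_roi()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_slab_phantom(
    speed: float = 0.0,
    noise: float = 0.0,
    surface: dict | None = None,
    grid=(40, 24, 8),
    depth_range=(50.0, 170.0),
    pitch: float = 10.0,
    seed: int = 0,
    w: float = 4.0,
) -> PhantomSpec:
    """Phantom whose single vessel layer is a full-field slab: every
    voxel in the depth range flows at `speed`, handy for population
    statistics of the decorrelation metric."""
    n_z, n_x, n_y = grid
    return PhantomSpec(
        grid=grid,
        axial_pitch_um=pitch,
        surface_profile=surface or {"type": "flat", "z0": 10.0},
        vessel_layers=(
            VesselLayer(
                name="slab",
                depth_range_um=depth_range,
                disks=(Disk((n_x / 2.0, n_y / 2.0), 4.0 * (n_x + n_y)),),
                flow_speed_um_ms=speed,
            ),
        ),
        static_tissue_amplitude=1.0,
        speckle=SpeckleModel(resolution_radius_um=w, noise_floor_sigma=noise),
        seed=seed,
    )


def slab_pattern(tau: float = 1.5, grid=(40, 24, 8), repeats: int = 3) -> ScanPattern:
    n_z, n_x, n_y = grid
    return ScanPattern(n_x, n_y, repeats, tau, (n_x * 0.01, n_y * 0.01), "slab")


@pytest.fixture
def slab_phantom_factory():
    return make_slab_phantom


@pytest.fixture
def slab_pattern_factory():
    return slab_pattern
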