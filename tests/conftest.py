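import numpy as np
import pytest

from smartact.geometry import Point3D, VoxelGrid
from smartact.phantom import CellSpec, PhantomSpec, render_stack


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    """Reference voxel pitch on a grid small enough for fast rendering."""
    return VoxelGrid((96, 96, 60))


@pytest.fixture(scope="session")
def sparse_scene(small_grid):
    """One pipette cone and one soma, noiseless; returns (spec, pip, cells, truth)."""
    spec = PhantomSpec(grid=small_grid, tip_truth=Point3D(60.0, 60.0, 70.0),
                       cells=(CellSpec(Point3D(45.0, 45.0, 45.0)),), seed=7)
    pip, cells, truth = render_stack(spec)
    return spec, pip, cells, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
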