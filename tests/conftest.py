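import numpy as np
import pytest

from liverbrachy.geometry import VoxelGrid
from liverbrachy.mc_engine import TreatmentPlan


@pytest.fixture(scope="session")
def water():
    from liverbrachy.physics_data import load_material
    return load_material("water")


@pytest.fixture(scope="session")
def liver():
    from liverbrachy.physics_data import load_material
    return load_material("liver")


@pytest.fixture
def small_grid():
    """A 20^3 grid, 2 mm isotropic, centred on the origin."""
    spacing = np.array([2.0, 2.0, 2.0])
    origin = -(20 - 1) / 2.0 * spacing
    return VoxelGrid(np.zeros((20, 20, 20)), spacing, origin)


@pytest.fixture
def single_dwell_plan():
    return TreatmentPlan(
        dwell_positions=np.zeros((1, 3)),
        dwell_times=np.array([300.0]),
        source_strength_U=40700.0,
        prescription_Gy=15.0,
    )
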