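import numpy as np
import pytest

from chondrosim.geometry import voxelize_geometry
from chondrosim.solver import MaterialProps
from chondrosim.types import EllipsoidCell, EllipsoidSet


@pytest.fixture(scope="session")
def props():
    return MaterialProps()


def make_sphere_geometry(radius_um=8.0, box_um=40.0, n=32, electrode_axis=0):
    cell = EllipsoidCell(np.full(3, box_um / 2), np.full(3, radius_um), np.eye(3), 1)
    cells = EllipsoidSet([cell], np.full(3, box_um))
    return voxelize_geometry(cells, np.full(3, box_um), box_um / n, electrode_axis)


@pytest.fixture(scope="session")
def sphere_geometry():
    """R = 8 µm sphere centered in a 40 µm box at 32³."""
    return make_sphere_geometry()


@pytest.fixture(scope="session")
def clean_population_stack():
    """Six non-touching cells rendered noise-free at 0.5 µm voxels."""
    from chondrosim.synthetic import NoiseModel, render_stack, sample_population

    pop = sample_population(6, (80, 80, 80), allow_touching=False, seed=3)
    stack, gt = render_stack(pop, (0.5, 0.5, 0.5), NoiseModel())
    return pop, stack, gt
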