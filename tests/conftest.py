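import numpy as np
import pytest

from csieval import (DoseGrid, PhantomSpec, StructureMask, fp_recipe,
                     generate_dose, generate_phantom, s_recipe)

COARSE = dict(grid_shape=(50, 50, 125), spacing_mm=(4.0, 4.0, 4.0))


@pytest.fixture(scope="session")
def coarse_phantom():
    """4 mm phantom shared by the fast tests."""
    template, masks = generate_phantom(PhantomSpec(**COARSE, seed=7))
    return template, masks


@pytest.fixture(scope="session")
def coarse_doses(coarse_phantom):
    template, masks = coarse_phantom
    rng = np.random.default_rng(11)
    dose_fp = generate_dose(template, masks, fp_recipe(), rng)
    dose_s = generate_dose(template, masks, s_recipe(), rng)
    return dose_fp, dose_s


@pytest.fixture()
def ramp_box():
    """A 10x10x20 box with dose rising linearly 0 -> 20 Gy along z."""
    shape = (10, 10, 20)
    z = np.broadcast_to(np.linspace(0.0, 20.0, shape[2]), shape)
    grid = DoseGrid(z.copy(), (2.0, 2.0, 2.0))
    mask = StructureMask("box", np.ones(shape, dtype=bool), (2.0, 2.0, 2.0))
    return grid, mask
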