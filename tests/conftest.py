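import numpy as np
import pytest

from spherepipe.holo import QPImage
from spherepipe.models import Grid, SphereParams, projection_phase

# canonical imaging conditions used across the suite (aqueous medium,
# green illumination, camera pixels ~0.1 um)
WL = 550e-9
PX = 0.107e-6
NMED = 1.335


@pytest.fixture
def grid200():
    return Grid(shape=(200, 200), pixel_size=0.1e-6, wavelength=WL,
                medium_index=NMED)


def make_projection_qpi(grid, n=1.36, r=5e-6, cx=None, cy=None,
                        noise_sigma=0.0, seed=0, offset=0.0):
    """Projection-model sphere phantom as a QPImage."""
    H, W = grid.shape
    p = SphereParams(n=n, r=r,
                     cx=W / 2 if cx is None else cx,
                     cy=H / 2 if cy is None else cy,
                     phase_offset=offset)
    phase = projection_phase(p, grid)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0, noise_sigma, grid.shape)
    qpi = QPImage(phase=phase, amplitude=np.ones(grid.shape),
                  wavelength=grid.wavelength, pixel_size=grid.pixel_size,
                  medium_index=grid.medium_index)
    return qpi, p
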