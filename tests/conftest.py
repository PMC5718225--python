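import numpy as np
import pytest

from dirqa import Grid, VectorField
from dirqa.synthetic import FieldSpec, analytic_field


@pytest.fixture
def aniso_grid() -> Grid:
    """Small grid with the package's default anisotropic CT-like spacing."""
    return Grid(shape=(16, 16, 12), spacing=(1.0, 1.0, 2.5))


@pytest.fixture
def rotation_field(aniso_grid) -> VectorField:
    """Rigid rotation u = omega x r with omega = (0, 0, 0.1); curl = 2*omega."""
    return analytic_field(FieldSpec("rotation", {"omega": (0.0, 0.0, 0.1)}), aniso_grid)


def random_smooth_field(grid: Grid, seed: int, amplitude: float = 1.0) -> VectorField:
    """Seeded random smooth field (Gaussian-filtered white noise), for oracles."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    comps = [
        gaussian_filter(rng.normal(0.0, amplitude, grid.shape), sigma=2.0)
        for _ in range(3)
    ]
    return VectorField(grid, *comps)
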