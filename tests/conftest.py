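import numpy as np
import pytest
import scipy.ndimage as ndi

from ringfwi import (
    BornSeriesSettings,
    Grid,
    RingArraySpec,
    SlownessField,
)


# coarse test grids legitimately sit near the sampling limit; the solver
# warns there, which is expected and not a failure signal
@pytest.fixture(autouse=True)
def _quiet_sampling_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*points per minimum wavelength.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_medium(grid: Grid, rng, c0=1500.0, amplitude=50.0, corr=3.0) -> SlownessField:
    """Smooth random sound-speed map around c0 (helper, not a fixture)."""
    bump = ndi.gaussian_filter(rng.standard_normal(grid.shape), corr)
    bump = bump / np.abs(bump).max()
    return SlownessField(grid, 1.0 / (c0 + amplitude * bump))


@pytest.fixture
def grid2d():
    return Grid.centered((32, 32), 1.5e-3)


@pytest.fixture
def medium2d(grid2d, rng):
    return smooth_medium(grid2d, rng)


@pytest.fixture
def oracle_settings():
    """Tight-tolerance series settings for comparisons against the LU oracle."""
    return BornSeriesSettings(tolerance=1e-10, max_iterations=6000, pad_width=10)


@pytest.fixture
def tiny_ring():
    return RingArraySpec(radius=16e-3, n_rows=1, n_elements_per_row=16, row_pitch=1.0)
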