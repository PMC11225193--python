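import numpy as np
import pytest

from callspace.space import DensityRegion, GridSpec
from callspace.synthetic import SimConfig, simulate_flocks

UNIT_GRID_10 = GridSpec(0.0, 10.0, 0.0, 10.0, 10, 10)


def region_from_mask(mask: np.ndarray, grid: GridSpec | None = None) -> DensityRegion:
    """Wrap an explicit occupancy mask as a DensityRegion (for IoU tests)."""
    mask = np.asarray(mask, dtype=bool)
    if grid is None:
        ny, nx = mask.shape
        grid = GridSpec(0.0, float(nx), 0.0, float(ny), nx, ny)
    return DensityRegion(grid=grid, bandwidth=(1.0, 1.0), level=0.95, mask=mask)


def random_mask(rng: np.random.Generator, shape=(10, 10), p: float = 0.4) -> np.ndarray:
    """Random non-empty boolean mask."""
    while True:
        mask = rng.random(shape) < p
        if mask.any():
            return mask


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """One flock per age class, 30 calls per bird and block."""
    return SimConfig(n_flocks_per_age=1, calls_per_bird_block=30, seed=11)


@pytest.fixture(scope="session")
def tiny_flocks(tiny_config):
    return simulate_flocks(tiny_config)


def tone(freq_hz: float, duration_s: float, rate: int = 22050, amp: float = 0.5) -> np.ndarray:
    t = np.arange(int(duration_s * rate)) / rate
    return amp * np.sin(2 * np.pi * freq_hz * t)
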