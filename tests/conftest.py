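import numpy as np
import pytest

from detomo.transport import PhaseGrid


@pytest.fixture(scope="session")
def slab_grid() -> PhaseGrid:
    """The benchmark 1-D slab grid: dx = 0.05, 16 directions."""
    return PhaseGrid.unit_interval(dx=0.05, n_angles=16)


@pytest.fixture(scope="session")
def square_grid() -> PhaseGrid:
    """The benchmark unit-square grid: dx = 0.05, 16 directions."""
    return PhaseGrid.unit_square(dx=0.05, n_angles=16)


@pytest.fixture(scope="session")
def coarse_square_grid() -> PhaseGrid:
    """A cheap unit-square grid for solver-heavy tests."""
    return PhaseGrid.unit_square(dx=0.1, n_angles=8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
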