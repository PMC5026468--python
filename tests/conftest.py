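import numpy as np
import pytest

from retmosaic import PointPattern, gen_dmin, gen_random

WINDOW = (0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def window():
    return WINDOW


@pytest.fixture
def random_pattern():
    return gen_random(500, WINDOW, seed=42)


@pytest.fixture
def dmin_pattern():
    return gen_dmin(300, WINDOW, dmin=40.0, seed=7)


@pytest.fixture
def grid_pattern():
    """3x3 unit grid in a window that exactly covers it."""
    xs, ys = np.meshgrid([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    return PointPattern(
        points=np.column_stack([xs.ravel(), ys.ravel()]), window=(0, 0, 2, 2)
    )
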