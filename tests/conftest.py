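import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from subgen.core import ActivityMatrix
from subgen.gridsim import GridModuleSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_matrix(rng):
    return ActivityMatrix(rng.standard_normal((8, 30)))


@pytest.fixture()
def matrix_pair(rng):
    a = ActivityMatrix(rng.standard_normal((10, 40)))
    b = ActivityMatrix(rng.standard_normal((10, 40)))
    return a, b


@pytest.fixture(scope="session")
def tiny_module_spec():
    """A desk-scale grid module: 12×12 phase lattice, 25×25 box bins."""
    return GridModuleSpec(
        spacing=2.0, orientation=0.3, phase_lattice=(12, 12),
        box_size=10.0, resolution=25,
    )
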