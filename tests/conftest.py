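import numpy as np
import pytest

from mzkit.data_model import AttributeRasterStack, GridGeometry, LabelRaster


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_geometry():
    return GridGeometry(x0=0.0, y0=0.0, cell_size=5.0, ncols=4, nrows=3)


@pytest.fixture
def quadrant_labels():
    """20x20 grid split into four 10x10 quadrant zones."""
    geom = GridGeometry(0.0, 0.0, 5.0, 20, 20)
    labels = np.zeros((20, 20), dtype=int)
    labels[:10, 10:] = 1
    labels[10:, :10] = 2
    labels[10:, 10:] = 3
    return LabelRaster(geom, labels, np.ones((20, 20), dtype=bool))


@pytest.fixture
def quadrant_stack(quadrant_labels, rng):
    """Stack of three attributes whose means separate the four quadrants."""
    geom = quadrant_labels.geometry
    means = {
        "MC": np.array([0.0, 10.0, 20.0, 30.0]),
        "OC": np.array([30.0, 20.0, 10.0, 0.0]),
        "CEC": np.array([0.0, 20.0, 10.0, 30.0]),
    }
    layers = {
        name: m[quadrant_labels.labels] + rng.normal(0, 0.5, geom.shape)
        for name, m in means.items()
    }
    return AttributeRasterStack(geom, quadrant_labels.mask.copy(), layers)
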