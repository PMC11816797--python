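import numpy as np
import pytest

from siliquant import SyntheticSiliqueSpec, generate_capsule


@pytest.fixture
def straight_capsule():
    """Axis-aligned capsule, centerline 100 px, constant radius 5 px."""
    spec = SyntheticSiliqueSpec(centerline=[[0, 0], [100, 0]], radius_profile=[5.0])
    inst, truth = generate_capsule(spec)
    return inst, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def line_mask(pixels, shape=None):
    """Build a binary raster from a list of (row, col) pixels."""
    pixels = list(pixels)
    if shape is None:
        shape = (max(r for r, _ in pixels) + 2, max(c for _, c in pixels) + 2)
    arr = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        arr[r, c] = True
    return arr
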