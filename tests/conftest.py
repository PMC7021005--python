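import numpy as np
import pytest

from mlctip.dose import GridSpec, KernelParams
from mlctip.mlc import BeamModelParams, LeafPairAperture, Segment


def make_bank(openings, pitch_mm=5.0):
    """Small leaf bank from a list of (left, right) openings, centered on y=0."""
    n = len(openings)
    y0 = -n * pitch_mm / 2.0
    return tuple(
        LeafPairAperture(i, y0 + i * pitch_mm, y0 + (i + 1) * pitch_mm, l, r)
        for i, (l, r) in enumerate(openings)
    )


def uniform_segment(left, right, n_pairs=8, mu=1.0, gantry=0.0):
    return Segment(make_bank([(left, right)] * n_pairs), mu, gantry)


def random_bank(rng, n_pairs=8, span=30.0):
    openings = []
    for _ in range(n_pairs):
        a, b = np.sort(rng.uniform(-span, span, size=2))
        openings.append((a, b))
    return make_bank(openings)


@pytest.fixture
def model():
    return BeamModelParams(leaf_tip_offset_mm=-0.5, leaf_tip_width_mm=4.5)


@pytest.fixture
def small_grid():
    """Grid just covering an 8-pair (40 mm) test bank."""
    return GridSpec(origin_mm=(-40.0, -20.0), spacing_mm=1.0, nx=81, ny=41)


@pytest.fixture
def kernel():
    return KernelParams()
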