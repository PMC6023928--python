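"""Shared fixtures: fast compact phantoms and the (expensive) full-grid
five-seed recovery run used by the end-to-end accuracy tests."""

from __future__ import annotations

import numpy as np
import pytest

from octd.phantom import PhantomSpec
from octd.study import compact_overrides, morphometry_pipeline


def make_compact_spec(**overrides) -> PhantomSpec:
    """A phantom on a small en-face crop: full axial sampling, fast to render."""
    params = dict(compact_overrides())
    params.update(overrides)
    return PhantomSpec(**params)


def make_tiny_spec(**overrides) -> PhantomSpec:
    """A very small, coarse phantom for I/O and plumbing tests."""
    params = dict(
        grid_shape=(128, 32, 40),
        spacing_air=(5000.0 / 128, 35.0, 27.34375),
        punctum_yx=(560.0, 300.0),
        flask_max_radius=120.0,
        horizontal_transverse_width=500.0,
        horizontal_length=400.0,
        muscle_thickness=80.0,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def compact_spec() -> PhantomSpec:
    return make_compact_spec()


@pytest.fixture(scope="session")
def five_seed_recovery():
    """Full default-grid phantoms, five seeds, measured end to end.

    Shared by the geometry-recovery and segmentation-quality tests; this is
    the expensive part of the suite (~1 min).
    """
    return [morphometry_pipeline(PhantomSpec(rng_seed=s)) for s in range(5)]
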