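"""Shared fixtures: small phantoms and cheap geometry helpers.

Everything is generated programmatically at test time; session scope keeps
the expensive phantom builds to one per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from doseaccum.core import GridGeometry, ImageVolume, Modality, StructureMask
from doseaccum.synthetic import (
    CourseParams,
    DegradationParams,
    PhantomParams,
    build_phantom,
    simulate_course,
)

#: compact phantom for fast unit tests (not the acceptance-scale grid)
SMALL_GEOMETRY = GridGeometry.centered((48, 48, 32), (5.0, 5.0, 6.0))
SMALL_CBCT_GEOMETRY = GridGeometry.centered((48, 48, 32), (5.0, 5.0, 5.0))


def small_phantom_params() -> PhantomParams:
    return PhantomParams(geometry=SMALL_GEOMETRY)


def short_course(seed: int = 0, **kw) -> CourseParams:
    """Two-week course with a consistent 20 Gy schedule for quick tests."""
    defaults = dict(
        n_weeks=2,
        fractions_per_week=5,
        fraction_dose_gy=2.0,
        total_dose_gy=20.0,
        seed=seed,
        cbct_geometry=SMALL_CBCT_GEOMETRY,
    )
    defaults.update(kw)
    return CourseParams(**defaults)


@pytest.fixture(scope="session")
def phantom():
    """Default-scale phantom (96x96x64, 2.5 mm in-plane, 3 mm slices)."""
    return build_phantom(seed=1)


@pytest.fixture(scope="session")
def small_phantom():
    return build_phantom(small_phantom_params(), seed=1)


@pytest.fixture(scope="session")
def small_course(small_phantom):
    ct, masks = small_phantom
    studies = simulate_course(
        ct, masks, short_course(seed=3), DegradationParams(seed=3)
    )
    return ct, masks, studies


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(values, spacing=(2.0, 2.0, 2.0), origin=(0.0, 0.0, 0.0), modality=Modality.CT):
    values = np.asarray(values)
    return ImageVolume(GridGeometry(values.shape, spacing, origin), values, modality=modality)
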