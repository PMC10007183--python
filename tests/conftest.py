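"""Shared fixtures: geometry and datasets are session-scoped because the
leadfield and inverse operator are deterministic and reused by many tests."""

from __future__ import annotations

import numpy as np
import pytest

from fatiguefc.headmodel import (
    build_sensor_array,
    build_source_space,
    compute_leadfield,
)
from fatiguefc.inverse import compute_inverse_operator
from fatiguefc.parcellation import build_synthetic_atlas


@pytest.fixture(scope="session")
def sensors32():
    return build_sensor_array("standard_32", scalp_radius=0.100)


@pytest.fixture(scope="session")
def small_space():
    """64 vertices per hemisphere: the desk-scale source space."""
    return build_source_space(64, seed=0)


@pytest.fixture(scope="session")
def small_leadfield(sensors32, small_space):
    return compute_leadfield(sensors32, small_space)


@pytest.fixture(scope="session")
def small_atlas(small_space):
    """16 ROIs (8 per hemisphere) on the desk-scale space."""
    return build_synthetic_atlas(small_space, 8, seed=0)


@pytest.fixture(scope="session")
def small_inverse(small_leadfield):
    return compute_inverse_operator(small_leadfield)


@pytest.fixture(scope="session")
def medium_space():
    """162 vertices per hemisphere, used for localization checks."""
    return build_source_space(162, seed=1)


@pytest.fixture(scope="session")
def medium_leadfield(sensors32, medium_space):
    return compute_leadfield(sensors32, medium_space)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
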