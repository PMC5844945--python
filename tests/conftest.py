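"""Shared fixtures: small grids, masks, and a reusable synthetic cohort."""

import numpy as np
import pytest

from xeromics.grids import DoseGrid, OrganMask
from xeromics.synthetic import SimulationParams, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """Empty 30 mm cube at 1 mm spacing."""
    return DoseGrid(np.zeros((31, 31, 31)), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def ball_mask(geometry, center, radius) -> OrganMask:
    x, y, z = geometry.coordinate_grids()
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
    return OrganMask(inside, geometry.spacing, geometry.origin)


@pytest.fixture(scope="session")
def demo_cohort():
    """A 60-patient cohort at 2 mm spacing shared by pipeline-level tests."""
    return simulate_cohort(SimulationParams(n_patients=60, spacing=2.0, seed=2024))


@pytest.fixture(scope="session")
def demo_features(demo_cohort):
    return demo_cohort.extract_features()
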