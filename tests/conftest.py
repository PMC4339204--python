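"""Shared fixtures: surface machinery and small phantoms, session-scoped
because construction dominates test runtime."""

import numpy as np
import pytest

from craniage import phantom as phm
from craniage import surface as sf


@pytest.fixture(scope="session")
def control_mesh():
    return sf.default_annotated_sphere(2)


@pytest.fixture(scope="session")
def surf(control_mesh):
    return sf.Surface(control_mesh, depth=3)


@pytest.fixture(scope="session")
def sampling(control_mesh):
    return sf.sample_regular(control_mesh, 2)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Full-resolution noiseless phantom used by the fitting checks."""
    spec = phm.PhantomSpec(age=20.0, voxel_size=0.6, seed=1,
                           speckle_level=0.0)
    return phm.make_phantom(spec)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Small, fast phantom for feature-level tests."""
    spec = phm.PhantomSpec(age=24.0, voxel_size=1.5, seed=3)
    return phm.make_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
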