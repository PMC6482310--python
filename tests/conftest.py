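import numpy as np
import pytest

from ocapdt.cohort import CohortSpec, generate_cohort
from ocapdt.phantom import PhantomSpec, VesselSegment, generate_oct_volume


@pytest.fixture(scope="session")
def default_phantom():
    """Desk-scale default phantom, seed 1 (one 0.05 mm-radius vessel)."""
    return generate_oct_volume(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A fast phantom for tests that regenerate volumes repeatedly."""
    return PhantomSpec(
        grid_size=(32, 96, 96),
        voxel_size=(0.03, 0.0125, 0.0125),
        vessel_tree=[VesselSegment((0.5, 0.15, 0.6), (0.5, 1.05, 0.6), 0.05)],
        seed=1,
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
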