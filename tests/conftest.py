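import numpy as np
import pytest

from vesselgrow.coordinate_mapping import parameterize
from vesselgrow.synthetic_cohort import (
    StudyConditions,
    TubeSpec,
    initial_ring_metrics,
    make_tube_mesh,
)


@pytest.fixture(scope="session")
def tube_spec():
    return TubeSpec()


@pytest.fixture(scope="session")
def conditions():
    return StudyConditions()


@pytest.fixture(scope="session")
def cylinder_mesh(tube_spec):
    """Default straight reference tube (r=0.6 mm, L=3 mm, 64x40 grid)."""
    return make_tube_mesh(tube_spec)


@pytest.fixture(scope="session")
def cylinder_coords(cylinder_mesh):
    return parameterize(cylinder_mesh)


@pytest.fixture(scope="session")
def baseline_metrics(tube_spec):
    return initial_ring_metrics(tube_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
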