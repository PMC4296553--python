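import numpy as np
import pytest

import cumudose as cd


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_geometry():
    """A 16^3 lattice, 2 mm isotropic, centered at the origin."""
    return cd.GridGeometry((-15.0, -15.0, -15.0), (2.0, 2.0, 2.0),
                           (16, 16, 16), "ICBT1")


@pytest.fixture(scope="session")
def default_course():
    """The default 96^3 phantom course at seed 1, shared across tests."""
    return cd.generate_course(cd.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def injected_accumulation(default_course):
    """Accumulation of the default course with the ground-truth fields."""
    tc = cd.to_treatment_course(default_course)
    return cd.accumulate(tc, injected_fields=default_course.truth_fields,
                         dir_settings=None)


@pytest.fixture(scope="session")
def small_course():
    """A coarse (48^3, 3 mm) phantom course for fast structural tests."""
    spec = cd.PhantomSpec(seed=7, shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0))
    return cd.generate_course(spec)
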