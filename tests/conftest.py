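import numpy as np
import pytest

from chalign.alignment import AlignmentSchedule, AlignmentWorkspace
from chalign.surface import apply_polar_cap_mask, build_icosphere
from chalign.synthetic import CohortSpec, make_cohort


@pytest.fixture(scope="session")
def mesh2():
    """Order-2 left-hemisphere mesh (162 vertices), no mask."""
    return build_icosphere(2, 100.0, "left")


@pytest.fixture(scope="session")
def mesh3_masked():
    """Order-3 left mesh with a 20-degree polar-cap medial-wall stand-in."""
    return apply_polar_cap_mask(build_icosphere(3, 100.0, "left"), (1.0, 0.0, 0.0), 20.0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3 subjects, short movies, 2 localizer runs: fast structural tests."""
    spec = CohortSpec(n_subjects=3, movie_timepoints=120, n_localizer_runs=2)
    return make_cohort(spec, master_seed=123)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects at the default noise/structure conditions."""
    return make_cohort(CohortSpec(n_subjects=4), master_seed=321)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study cohort: 10 subjects, 2 movies, 4 localizer runs."""
    return make_cohort(CohortSpec(), master_seed=20)


@pytest.fixture(scope="session")
def default_workspace(default_cohort):
    return AlignmentWorkspace(default_cohort.mesh_pair)
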