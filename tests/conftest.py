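import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oligotriage.cohort import add_idh1_r132h_column, build_cohort_fixture
from oligotriage.simulate import SimImageParams


@pytest.fixture(scope="session")
def cohort():
    """The reconstructed 145-case cohort table."""
    return build_cohort_fixture()


@pytest.fixture(scope="session")
def cohort_markers(cohort):
    """Cohort with the IDH1-R132H immunostain surrogate column appended."""
    return add_idh1_r132h_column(cohort)


@pytest.fixture
def small_params():
    """Small, quick-to-render field parameters for image tests."""
    return SimImageParams(
        image_size=128,
        n_tumor_nuclei=15,
        n_control_cells=2,
        nucleus_radius_range=(4, 6),
        seed=0,
    )
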