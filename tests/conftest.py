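import numpy as np
import pytest

from vocstack import SimulationConfig, generate_cohort
from vocstack.core import Role


SMALL = SimulationConfig(
    seed=11, n_psc=4, n_psc_ibd=4, n_ibd=10, n_features_fecal=8,
    n_features_breath=6, n_markers=2, n_mc_blanks=4, n_instrument_blanks=2,
    n_qc=1, missing_rate=0.1,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for unit tests (not the study conditions)."""
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study-design defaults."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture()
def small_bio(small_cohort):
    fecal, _, _ = small_cohort
    return fecal.subset_samples(fecal.role_mask(Role.BIOLOGICAL))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
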