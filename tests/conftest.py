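import numpy as np
import pytest

import hsretina as hs


@pytest.fixture(scope="session")
def grid91():
    return hs.human_grid()


@pytest.fixture(scope="session")
def basis(grid91):
    return hs.build_constituent_basis(grid91)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Identifiable cohort: 2 distinct dominant nuisance axes, strong signal."""
    matrix, truth = hs.simulate_cohort(hs.recovery_cohort_config(seed=0))
    return matrix, truth


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the realistic study conditions (15 cases / 20 controls)."""
    matrix, truth = hs.simulate_cohort(hs.SyntheticCohortConfig(seed=11))
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
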