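import numpy as np
import pytest

from sortedmeth import CohortConfig, assign_phenotype, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-structure cohort at reduced site count."""
    config = CohortConfig(n_sites=2500, seed=101)
    sheet, beta, annotation = generate_cohort(config)
    return config, sheet, beta, annotation


@pytest.fixture(scope="session")
def labelled(cohort):
    """Same cohort with a 50/50 individual-level phenotype."""
    config, sheet, beta, annotation = cohort
    return config, assign_phenotype(sheet, 0.5, 11), beta, annotation


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for per-site model comparisons."""
    config = CohortConfig(n_individuals=60, availability=(55, 50, 52),
                          n_sites=120, seed=7)
    sheet, beta, annotation = generate_cohort(config)
    sheet = assign_phenotype(sheet, 0.5, 3)
    return config, sheet, beta, annotation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
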