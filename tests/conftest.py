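import numpy as np
import pandas as pd
import pytest

from tallsub.cohort import CohortConfig, default_specs, generate_cohort, with_effect_size


@pytest.fixture(scope="session")
def small_cohort():
    """230-sample cohort at published frequencies, default effect size."""
    return generate_cohort(CohortConfig(n_samples=230, seed=11), default_specs())


@pytest.fixture(scope="session")
def tiny_cohort():
    """60-sample cohort for cheap structural checks."""
    return generate_cohort(CohortConfig(n_samples=60, n_cpgs=600, seed=5), default_specs())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
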