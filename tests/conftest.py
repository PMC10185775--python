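import numpy as np
import pytest

from svmeo import EOConfig, default_cohort_spec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def study_shaped_table():
    """One study-shaped cohort: 80 eyes, 22 features, 3 groups."""
    return generate(default_cohort_spec(seed=7), rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def null_table():
    """A cohort with no group effects at all."""
    return generate(
        default_cohort_spec(effect_scale=0.0, seed=8), rng=np.random.default_rng(8)
    )


@pytest.fixture
def small_eo_config():
    return EOConfig(population_size=6, max_iterations=8, seed=0)
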