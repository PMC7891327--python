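import numpy as np
import pandas as pd
import pytest

from gdmscreen import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A complete synthetic cohort small enough for fast unit tests."""
    return generate_cohort(GeneratorConfig(n_subjects=800, seed=11))


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """A mid-size cohort for fits that need a few hundred cases."""
    return generate_cohort(GeneratorConfig(n_subjects=8000, seed=23))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
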