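import numpy as np
import pytest

from mrcea.cohort import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def prostate_like():
    """One deterministic prostate-cancer-like cohort at analysis scale."""
    params = GeneratorParams.realistic(20_000, seed=0)
    cohort, dosages, weights, truth = generate_cohort(params)
    return params, cohort, dosages, weights, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 4,000-person cohort for structural tests."""
    params = GeneratorParams.realistic(4_000, seed=11)
    cohort, dosages, weights, truth = generate_cohort(params)
    return params, cohort, dosages, weights, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
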