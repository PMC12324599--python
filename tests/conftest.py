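import numpy as np
import pytest

from sldscreen import SyntheticCorpusConfig, default_prevalence_table, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Eight annotated subjects over the 11 included scenarios."""
    return generate_corpus(SyntheticCorpusConfig(n_subjects=8, seed=11))


@pytest.fixture(scope="session")
def zero_prevalence():
    """Default prevalence table with every planting probability set to 0."""
    prev = default_prevalence_table()
    prev.loc[:, :] = 0.0
    return prev


@pytest.fixture(scope="session")
def negative_corpus(zero_prevalence):
    """A corpus of subjects with no planted features (all labels 0)."""
    return generate_corpus(
        SyntheticCorpusConfig(
            n_subjects=10, seed=5, prevalence=zero_prevalence, scenarios=("S3", "S4", "S5")
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
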