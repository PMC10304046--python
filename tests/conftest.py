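import pytest
from hypothesis import settings

from suppnlp import GeneratorConfig, generate_corpus, load_lexicon

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """A compact deterministic corpus shared by read-only tests."""
    return generate_corpus(
        GeneratorConfig(n_patients=25, notes_per_patient=3, seed=11), lexicon
    )


@pytest.fixture(scope="session")
def labeled_obs(small_corpus, lexicon):
    return small_corpus.labeled_observations(lexicon)
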