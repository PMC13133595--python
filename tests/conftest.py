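import pytest

from promscan import lexicon_matcher, synthetic_corpus


@pytest.fixture(scope="session")
def lexicon():
    return lexicon_matcher.load_default_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """200-study seeded corpus with traps, exact plants only."""
    config = synthetic_corpus.SyntheticConfig(
        n_studies=200,
        seed=42,
        prevalence=0.33,
        negative_traps=synthetic_corpus.TrapRates(0.2, 0.2, 0.2),
    )
    return synthetic_corpus.generate_corpus(config)


@pytest.fixture(scope="session")
def small_outcomes(small_corpus):
    studies, _ = small_corpus
    return [o for s in studies for o in s.outcomes]
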