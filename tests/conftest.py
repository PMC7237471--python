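import pytest

from plastidome.greedy import AlignmentScorer
from plastidome.simulate import simulate_corpus, simulate_hit_table
from plastidome.types import default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def corpus(taxonomy):
    """Well-separated synthetic families shared across clustering tests.

    Within-family pairwise identity ~0.7, between-family ~ background
    (~0.05), so both clustering methods should recover the partition
    exactly.
    """
    return simulate_corpus(
        n_families=10,
        taxonomy=taxonomy,
        rng_seed=11,
        within_identity=0.7,
        paralog_mean=0.3,
        length_range=(120, 260),
    )


@pytest.fixture(scope="session")
def corpus_hits(corpus):
    return simulate_hit_table(corpus, rng_seed=11)


@pytest.fixture(scope="session")
def shared_scorer():
    """One memoised aligner for the whole session (pure cache, no state)."""
    return AlignmentScorer()
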