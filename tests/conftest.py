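import numpy as np
import pytest

import raterstack as rs
from raterstack.vocabulary import FeatureVocabulary, Question


@pytest.fixture(scope="session")
def vocab():
    return rs.default_vocabulary()


@pytest.fixture(scope="session")
def tiny_vocab():
    """Three questions with differing choice counts, for fast data-model tests."""
    return FeatureVocabulary(
        questions=(
            Question("q01", "eye contact", ("clear", "partial", "rare", "absent")),
            Question("q02", "responds to name", ("yes", "sometimes", "no")),
            Question("q03", "points", ("yes", "no")),
        )
    )


def make_table(n_per_class=10, seed=0, archetypes=None, profiles=None, vocab=None,
               missingness=0.02):
    """Small simulated annotation table shared across test modules."""
    vocab = vocab or rs.default_vocabulary()
    spec = rs.CohortSpec(
        n_asd=n_per_class,
        n_slc=n_per_class,
        n_td=n_per_class,
        archetypes=archetypes or rs.default_archetypes(vocab),
        seed=seed,
        vocabulary=vocab,
    )
    cohort = rs.generate_cohort(spec)
    profiles = profiles or rs.default_profiles(vocab, missingness=missingness)
    return rs.simulate_raters(cohort, profiles, seed=seed + 1)


@pytest.fixture(scope="session")
def small_table():
    return make_table(n_per_class=12, seed=42)
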