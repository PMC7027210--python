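from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grantminer import resources
from grantminer.data_model import GrantRecord
from grantminer.lexicon import Lexicon, LexiconEntry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_lexicon():
    return resources.demo_lexicon()


@pytest.fixture(scope="session")
def demo_type_lexicon():
    return resources.demo_type_lexicon()


@pytest.fixture(scope="session")
def country_table():
    return resources.demo_country_table()


@pytest.fixture
def tiny_lexicon():
    """Three diseases incl. a substring pair, for tie-break tests."""
    return Lexicon(
        [
            LexiconEntry("stroke", "Stroke", "Cardiovascular diseases", "Non-communicable"),
            LexiconEntry("breast cancer", "Breast cancer", "Malignant neoplasms", "Non-communicable"),
            LexiconEntry("cancer", "Other cancers", "Malignant neoplasms", "Non-communicable"),
            LexiconEntry(
                "dengue",
                "Dengue",
                "Infectious and parasitic diseases",
                "Communicable, maternal, perinatal and nutritional conditions",
                ntd=True,
            ),
        ]
    )


def make_grant(gid="G1", title="", abstract=None, funder="NIH", **kw) -> GrantRecord:
    return GrantRecord(grant_id=gid, funder=funder, title=title, abstract=abstract, **kw)


@pytest.fixture
def grant_factory():
    return make_grant


def random_synonym_pool(rng: np.random.Generator, n: int) -> list[str]:
    """Random normalised synonyms: 1-3 short lowercase words each."""
    words = [
        "".join(rng.choice(list("abcdefgh"), size=rng.integers(2, 6)))
        for _ in range(max(4, n))
    ]
    pool = set()
    while len(pool) < n:
        k = int(rng.integers(1, 4))
        pool.add(" ".join(rng.choice(words, size=k)))
    return sorted(pool)


def random_text(rng: np.random.Generator, vocab: list[str], n_words: int) -> str:
    return " ".join(rng.choice(vocab, size=n_words)) if n_words else ""
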