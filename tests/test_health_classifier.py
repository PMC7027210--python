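"""The earliest-match single-label health classifier vs independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from grantminer.health_classifier import (
    classify_corpus,
    classify_health,
    find_first_match,
    normalize_text,
)
from grantminer.lexicon import Lexicon, LexiconEntry

from _oracle import naive_first_match, oracle_classify
from conftest import make_grant, random_synonym_pool, random_text


class TestNormalizeText:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("  Breast‐Cancer   Genomics ", "breast-cancer genomics"),
            ("", ""),
            ("HIV/AIDS cohort", "hiv aids cohort"),
            ("Étude de la dengue", "etude de la dengue"),
            ("tabs\tand\nnewlines", "tabs and newlines"),
            ("trailing hyphen- here", "trailing hyphen here"),
            (None, ""),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_text(raw) == expected

    @given(st.text(max_size=80))
    def test_idempotent(self, raw):
        once = normalize_text(raw)
        assert normalize_text(once) == once

    @given(st.text(max_size=80))
    def test_output_alphabet(self, raw):
        out = normalize_text(raw)
        assert set(out) <= set("abcdefghijklmnopqrstuvwxyz0123456789- ")
        assert "  " not in out


def _lex(*synonyms):
    return Lexicon(
        [
            LexiconEntry(s, f"D-{s}", "Sub", "Non-communicable")
            for s in synonyms
        ]
    )


class TestFindFirstMatch:
    def test_minimum_offset_wins(self, tiny_lexicon):
        hit = find_first_match("studies of stroke and breast cancer", tiny_lexicon)
        assert (hit.offset, hit.synonym) == (11, "stroke")
        assert hit.entry.subcategory == "Cardiovascular diseases"

    def test_word_boundary_blocks_embedded_match(self):
        assert find_first_match("influences of fluid shear", _lex("flu")) is None

    def test_empty_text(self, tiny_lexicon):
        assert find_first_match("", tiny_lexicon) is None

    def test_tie_at_same_offset_prefers_longest(self):
        hit = find_first_match("breast cancer", _lex("breast cancer", "cancer", "breast"))
        assert hit.synonym == "breast cancer"
        assert hit.offset == 0

    def test_hyphen_does_not_block_boundary(self):
        assert find_first_match("flu-like illness", _lex("flu")).offset == 0

    @given(st.data())
    def test_matches_naive_all_offsets_oracle(self, data):
        """Property: exact agreement with the fully naive quadratic scan."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        synonyms = random_synonym_pool(rng, int(rng.integers(1, 12)))
        vocab = list({w for s in synonyms for w in s.split()}) + ["zz", "qq", "xo"]
        text = random_text(rng, vocab, int(rng.integers(0, 15)))
        hit = find_first_match(text, _lex(*synonyms))
        expected = naive_first_match(text, synonyms)
        got = None if hit is None else (hit.offset, hit.synonym)
        assert got == expected


class TestClassifyHealth:
    def test_title_match_shadows_abstract(self, demo_lexicon):
        g = make_grant(title="alzheimer biomarkers", abstract="hiv cohort follow-up")
        r = classify_health(g, demo_lexicon)
        assert r.source_field == "title"
        assert r.disease == "Alzheimer disease and other dementias"
        assert r.subcategory == "Neurological conditions"

    def test_fallback_to_abstract(self, demo_lexicon):
        g = make_grant(
            title="novel capacity programme", abstract="dengue vector control study"
        )
        r = classify_health(g, demo_lexicon)
        assert (r.source_field, r.disease, r.ntd) == ("abstract", "Dengue", True)

    def test_no_match_anywhere_is_unclassified(self, demo_lexicon):
        r = classify_health(make_grant(title="", abstract=None), demo_lexicon)
        assert r.source_field == "none"
        assert r.disease is None and r.offset is None and r.matched_synonym is None

    def test_single_label_always(self, demo_lexicon):
        g = make_grant(title="stroke and breast cancer and dengue")
        r = classify_health(g, demo_lexicon)
        assert r.disease == "Stroke"  # exactly one disease, the earliest


class TestClassifyCorpus:
    def test_counts_and_unclassified(self, demo_lexicon):
        grants = [
            make_grant("A", title="malaria transmission"),
            make_grant("B", title="lab methods", abstract="zika serology"),
            make_grant("C", title="pure mathematics"),
        ]
        frame = classify_corpus(grants, demo_lexicon)
        assert len(frame) == 3
        assert (frame["source_field"] != "none").sum() == 2
        assert frame.set_index("grant_id").loc["C", "source_field"] == "none"

    def test_order_independence(self, demo_lexicon):
        grants = [
            make_grant("A", title="malaria transmission"),
            make_grant("B", abstract="zika serology", title="x"),
            make_grant("C", title="pure maths"),
        ]
        a = classify_corpus(grants, demo_lexicon)
        b = classify_corpus(list(reversed(grants)), demo_lexicon)
        assert a.equals(b)

    def test_empty_corpus(self, demo_lexicon):
        assert len(classify_corpus([], demo_lexicon)) == 0


class TestOracleEquivalenceOnRandomCorpora:
    def test_agreement_with_field_priority_oracle(self):
        """Random corpora: classifier output identical to the brute-force
        oracle (all synonyms, boundary predicate, title-then-abstract)."""
        rng = np.random.default_rng(20160101)
        for _ in range(50):
            synonyms = random_synonym_pool(rng, int(rng.integers(1, 30)))
            lex = _lex(*synonyms)
            vocab = list({w for s in synonyms for w in s.split()}) + ["zz", "qq"]
            for gid in range(int(rng.integers(1, 20))):
                title = random_text(rng, vocab, int(rng.integers(0, 10)))
                abstract = (
                    random_text(rng, vocab, int(rng.integers(0, 25)))
                    if rng.random() < 0.7
                    else None
                )
                got = classify_health(make_grant(f"G{gid}", title, abstract), lex)
                expected = oracle_classify(title, abstract, synonyms)
                if expected is None:
                    assert got.source_field == "none"
                else:
                    assert (got.source_field, got.offset, got.matched_synonym) == expected

    def test_monotonicity_adding_synonym_never_unclassifies(self):
        rng = np.random.default_rng(7)
        synonyms = random_synonym_pool(rng, 10)
        vocab = list({w for s in synonyms for w in s.split()})
        lex_small = _lex(*synonyms[:5])
        lex_big = _lex(*synonyms)
        for _ in range(100):
            text = random_text(rng, vocab, int(rng.integers(0, 12)))
            if find_first_match(text, lex_small) is not None:
                assert find_first_match(text, lex_big) is not None
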