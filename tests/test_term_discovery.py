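"""Frequency-ranked term discovery: single tokens, phrase contexts,
floors and the subset-recall candidate filter."""

import random
from collections import Counter

import pytest

from conftest import split_tokens
from filterforge.medline_corpus import Citation
from filterforge.term_discovery import (
    DEFAULT_STOPLIST, CandidateTerm, apply_floors, candidate_filter,
    discover_candidates, phrase_contexts, single_term_frequencies,
)


def _cit(i, title="", abstract=""):
    return Citation(pmid=str(i), title=title, abstract=abstract)


class TestSingleTermFrequencies:
    def test_two_identical_titles(self):
        subset = [_cit(1, "cardiac failure cases"), _cit(2, "cardiac failure cases")]
        ranked = dict((tok, (raw, rec)) for tok, raw, rec in single_term_frequencies(subset))
        assert ranked["cardiac"] == (2, 2)

    def test_toy_subset_matches_hand_count(self):
        subset = [
            _cit(1, "alpha beta", "beta gamma"),
            _cit(2, "beta", "delta"),
            _cit(3, "gamma gamma", ""),
        ]
        assert single_term_frequencies(subset) == [
            ("beta", 3, 2), ("gamma", 3, 2), ("alpha", 1, 1), ("delta", 1, 1),
        ]

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            single_term_frequencies([])

    def test_raw_frequency_matches_bruteforce_recount(self, regime_corpus):
        subset = list(regime_corpus)[:500]
        expected = Counter()
        for c in subset:
            expected.update(split_tokens(c.title) + split_tokens(c.abstract))
        for tok, raw, _ in single_term_frequencies(subset):
            assert raw == expected[tok]

    def test_invariant_to_record_order(self, regime_corpus):
        subset = list(regime_corpus)[:100]
        shuffled = subset[::-1]
        assert single_term_frequencies(subset) == single_term_frequencies(shuffled)


class TestApplyFloors:
    def test_frequency_ten_is_removed_eleven_kept(self):
        ranked = [("keepme", 11, 5), ("dropme", 10, 5)]
        assert apply_floors(ranked) == [("keepme", 11, 5)]

    def test_default_stoplist_drops_boilerplate(self):
        ranked = [("patients", 500, 100), ("failure", 50, 40)]
        assert apply_floors(ranked) == [("failure", 50, 40)]

    def test_no_floor_no_stoplist_is_identity(self):
        ranked = [("a", 1, 1), ("b", 2, 1)]
        assert apply_floors(ranked, min_frequency=0, stoplist=frozenset()) == ranked


class TestPhraseContexts:
    def test_planted_four_gram_is_listed(self):
        subset = [
            _cit(i, abstract=f"w{i} left ventricular systolic dysfunction w{i}")
            for i in range(29)
        ]
        found = dict(
            (phrase, (raw, rec))
            for phrase, raw, rec in phrase_contexts(subset, "systolic", min_frequency=10)
        )
        assert found["left ventricular systolic dysfunction"] == (29, 29)

    def test_absent_seed_yields_nothing(self):
        subset = [_cit(1, "alpha beta")]
        assert phrase_contexts(subset, "gamma", min_frequency=0) == []

    def test_counts_match_sliding_window_oracle(self):
        rng = random.Random(5)
        vocab = ["a", "b", "c", "d"]
        subset = [
            _cit(i, " ".join(rng.choices(vocab, k=8)), " ".join(rng.choices(vocab, k=15)))
            for i in range(30)
        ]
        raw_expected = Counter()
        rec_expected = Counter()
        for c in subset:
            seen = set()
            for field in (split_tokens(c.title), split_tokens(c.abstract)):
                for n in range(2, 6):
                    for i in range(len(field) - n + 1):
                        gram = " ".join(field[i:i + n])
                        raw_expected[gram] += 1
                        seen.add(gram)
            rec_expected.update(seen)
        for phrase, raw, rec in phrase_contexts(subset, "a", min_frequency=3):
            assert "a" in phrase.split()
            assert raw == raw_expected[phrase]
            assert rec == rec_expected[phrase]

    def test_record_occurrence_monotone_under_phrase_extension(self):
        rng = random.Random(11)
        vocab = ["x", "y", "z"]
        subset = [_cit(i, abstract=" ".join(rng.choices(vocab, k=20))) for i in range(40)]
        found = dict(
            (phrase, rec)
            for phrase, _, rec in phrase_contexts(subset, "x", min_frequency=1)
        )
        for phrase, rec in found.items():
            tokens = phrase.split()
            for n in range(2, len(tokens)):
                for i in range(len(tokens) - n + 1):
                    sub = " ".join(tokens[i:i + n])
                    if sub in found:
                        assert rec <= found[sub]


class TestCandidateFilter:
    def test_recall_just_above_cutoff_is_kept(self):
        subset = [_cit(i) for i in range(444)]
        kept = candidate_filter([("left ventricular diastolic dysfunction", 25, 23)], subset)
        assert len(kept) == 1 and kept[0].subset_recall == pytest.approx(23 / 444)

    def test_recall_exactly_at_cutoff_is_removed(self):
        subset = [_cit(i) for i in range(100)]
        assert candidate_filter([("some phrase", 6, 5)], subset) == []

    def test_blocklist_overrides_recall(self):
        subset = [_cit(i) for i in range(76)]
        kept = candidate_filter(
            [("chagas disease", 14, 14)], subset, blocklist={"Chagas disease"}
        )
        assert kept == []

    def test_matches_bruteforce_predicate(self):
        rng = random.Random(3)
        subset = [_cit(i) for i in range(200)]
        phrases = [(f"p{i} q{i}", rng.randint(5, 40), rng.randint(1, 30)) for i in range(50)]
        phrases = [(p, max(raw, rec), rec) for p, raw, rec in phrases]
        kept = {c.phrase for c in candidate_filter(phrases, subset, recall_cutoff=0.05)}
        assert kept == {p for p, _, rec in phrases if rec / 200 > 0.05}

    def test_record_occurrence_cannot_exceed_raw_frequency(self):
        with pytest.raises(ValueError, match="exceeds raw frequency"):
            CandidateTerm("x y", raw_frequency=3, record_occurrence=4,
                          subset_recall=0.1, source_subset="s")


def test_discover_candidates_agrees_with_stagewise_composition():
    """The fused per-subset discovery equals floors -> contexts -> filter
    run stage by stage."""
    rng = random.Random(9)
    vocab = [f"w{i}" for i in range(12)]
    subset = []
    for i in range(120):
        tokens = rng.choices(vocab, k=25)
        if rng.random() < 0.3:
            tokens[3:3] = ["cardiac", "failure"]
        subset.append(_cit(i, abstract=" ".join(tokens)))

    fused = discover_candidates(subset, min_frequency=10, recall_cutoff=0.05,
                                stoplist=DEFAULT_STOPLIST)

    singles = apply_floors(single_term_frequencies(subset))
    pooled: dict[str, tuple[str, int, int]] = {}
    for tok, _, _ in singles:
        for phrase, raw, rec in phrase_contexts(subset, tok, min_frequency=10):
            pooled[phrase] = (phrase, raw, rec)
    expected = candidate_filter(pooled.values(), subset, recall_cutoff=0.05)
    assert fused == expected
    assert any(c.phrase == "cardiac failure" for c in fused)
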