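"""Greedy maximum-coverage selection against reference and exhaustive oracles."""

import math
import random
from itertools import combinations

import pytest

from filterforge.medline_corpus import Citation, Corpus
from filterforge.greedy_selection import (
    exhaustive_select, greedy_select, term_recall,
)


def _instance(coverage: dict[str, set[int]], lost_size: int):
    """Build a corpus in which phrase p matches exactly the lost records in
    coverage[p]: record i's abstract lists the phrases that cover it."""
    phrase_tokens = {p: p.replace(" ", "") for p in coverage}
    citations = []
    for i in range(lost_size):
        words = [tok for p, tok in phrase_tokens.items() if i in coverage[p]]
        citations.append(Citation(pmid=str(i), abstract=" ".join(words) or "filler"))
    corpus = Corpus(citations)
    lost = {str(i) for i in range(lost_size)}
    phrases = {p: tok for p, tok in phrase_tokens.items()}
    return corpus, lost, list(phrases.values()), phrase_tokens


def _reference_greedy(coverage: dict[str, frozenset], individual: dict[str, int]):
    """Independent reimplementation: repeatedly take the max-gain phrase."""
    covered: set = set()
    order = []
    remaining = dict(coverage)
    while remaining:
        best = min(
            remaining,
            key=lambda p: (-len(remaining[p] - covered), -individual[p], p),
        )
        if not remaining[best] - covered:
            break
        order.append(best)
        covered |= remaining.pop(best)
    return order, covered


class TestTermRecall:
    def test_counts_matches_in_lost(self):
        corpus, lost, phrases, toks = _instance({"a b": {0, 1}, "c d": {2}}, 4)
        count, fraction = term_recall(toks["a b"], lost, corpus)
        assert (count, fraction) == (2, 0.5)

    def test_absent_phrase(self):
        corpus, lost, _, _ = _instance({"a b": {0}}, 3)
        assert term_recall("zz qq", lost, corpus) == (0, 0.0)

    def test_empty_lost_rejected(self):
        corpus, _, _, _ = _instance({"a b": {0}}, 1)
        with pytest.raises(ValueError, match="empty"):
            term_recall("a", set(), corpus)


class TestGreedySelect:
    def test_hand_traceable_instance(self):
        corpus, lost, _, toks = _instance(
            {"t one": {0, 1}, "t two": {1, 2}, "t three": {2}}, 3
        )
        result = greedy_select([toks["t one"], toks["t two"], toks["t three"]], lost, corpus)
        assert result.selected == (toks["t one"], toks["t two"])
        assert result.marginal_gains == (2, 1)
        assert result.rejected_redundant == (toks["t three"],)
        assert result.cumulative_recall[-1] == 1.0

    def test_single_candidate_selected_iff_positive_recall(self):
        corpus, lost, _, toks = _instance({"a b": {0}}, 2)
        assert greedy_select([toks["a b"]], lost, corpus).selected == (toks["a b"],)
        assert greedy_select(["zz qq"], lost, corpus).selected == ()

    def test_permutation_invariance(self):
        rng = random.Random(77)
        coverage = {f"p{i} x": set(rng.sample(range(40), rng.randint(1, 15))) for i in range(8)}
        corpus, lost, phrases, _ = _instance(coverage, 40)
        base = greedy_select(phrases, lost, corpus)
        for _ in range(5):
            rng.shuffle(phrases)
            assert greedy_select(phrases, lost, corpus) == base

    def test_gains_non_increasing_and_sum_to_coverage(self):
        rng = random.Random(13)
        for trial in range(20):
            coverage = {
                f"p{i} y": set(rng.sample(range(50), rng.randint(0, 20)))
                for i in range(rng.randint(1, 10))
            }
            corpus, lost, phrases, _ = _instance(coverage, 50)
            result = greedy_select(phrases, lost, corpus)
            gains = result.marginal_gains
            assert all(a >= b for a, b in zip(gains, gains[1:]))
            assert sum(gains) == len(result.covered)
            # Redundant terms add nothing to the selected coverage.
            union_all = set()
            for members in coverage.values():
                union_all |= members
            assert len(result.covered) == len(union_all)

    def test_matches_reference_greedy_and_exhaustive_bound(self):
        """On <= 12-candidate instances the selection must equal an
        independent greedy and cover >= (1 - 1/e) of the exhaustive optimum."""
        rng = random.Random(99)
        for trial in range(30):
            n_lost = rng.randint(10, 60)
            coverage_int = {
                f"c{i} z": set(rng.sample(range(n_lost), rng.randint(0, n_lost // 2)))
                for i in range(rng.randint(2, 12))
            }
            corpus, lost, phrases, toks = _instance(coverage_int, n_lost)
            result = greedy_select(phrases, lost, corpus)

            coverage = {
                toks[p]: frozenset(str(i) for i in members)
                for p, members in coverage_int.items()
            }
            individual = {p: len(cov) for p, cov in coverage.items()}
            ref_order, ref_covered = _reference_greedy(coverage, individual)
            assert list(result.selected) == ref_order
            assert result.covered == ref_covered

            k = len(result.selected)
            if k:
                _, optimum = exhaustive_select(phrases, lost, corpus, k=k)
                assert len(result.covered) >= (1 - 1 / math.e) * optimum


class TestExhaustive:
    def test_refuses_large_candidate_lists(self):
        corpus, lost, _, _ = _instance({f"p{i} w": {0} for i in range(13)}, 2)
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_select([f"p{i}w" for i in range(13)], lost, corpus)

    def test_finds_optimum_greedy_misses(self):
        # Classic greedy trap: the big middle set is picked first, forcing
        # three terms where two suffice; exhaustive finds the 2-term cover.
        coverage = {"mid dle": {1, 2, 3, 4}, "lef t": {0, 1, 2}, "rig ht": {3, 4, 5}}
        corpus, lost, phrases, toks = _instance(coverage, 6)
        combo, count = exhaustive_select(phrases, lost, corpus, k=2)
        assert count == 6
        assert set(combo) == {toks["lef t"], toks["rig ht"]}
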