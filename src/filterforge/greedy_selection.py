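"""Phase 5: greedy maximum-coverage selection of candidate terms.

Each candidate phrase is evaluated as a ``[tiab]`` search inside the full
Lost Set.  The best-retrieving term (T1) is selected first; every remaining
candidate is then offered in OR-combination with the current selection, and
the one adding the most not-yet-covered lost citations is selected next
(T2, T3, ...).  Selection stops when no candidate adds anything, which also
identifies and eliminates redundant terms -- those covering only citations
already reclaimed by preceding terms.

This is the standard greedy algorithm for maximum coverage, so its coverage
is guaranteed to be at least (1 - 1/e) of the optimal same-size
combination.  Ties are broken deterministically by higher individual recall
and then lexicographic phrase order, making the result invariant to
candidate ordering.  An exhaustive search over all k-term combinations is
available for small candidate lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from filterforge.medline_corpus import Corpus
from filterforge.retrieval_engine import match_phrase
from filterforge.term_discovery import CandidateTerm

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "term_recall", "greedy_select", "exhaustive_select"]


@dataclass(frozen=True)
class SelectionResult:
    """Ordered greedy selection with per-step marginal gains.

    ``marginal_gains[i]`` is the number of lost citations newly covered by
    ``selected[i]``; the sequence is non-increasing (submodularity of set
    cover) and sums to the total coverage.  ``cumulative_recall[i]`` is the
    covered fraction of the Lost Set after step i.  ``rejected_redundant``
    lists candidates that never added coverage at any step they were
    offered.
    """

    selected: tuple[str, ...]
    marginal_gains: tuple[int, ...]
    cumulative_recall: tuple[float, ...]
    rejected_redundant: tuple[str, ...]
    covered: frozenset[str]
    lost_size: int

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.marginal_gains):
            raise ValueError("selected terms must each add at least one citation")
        if any(a < b for a, b in zip(self.marginal_gains, self.marginal_gains[1:])):
            raise ValueError("marginal gains must be non-increasing")
        if sum(self.marginal_gains) != len(self.covered):
            raise ValueError("marginal gains must sum to the union coverage")

    @property
    def total_recall(self) -> float:
        return self.cumulative_recall[-1] if self.cumulative_recall else 0.0


def term_recall(phrase: str, lost: Iterable[str], corpus: Corpus) -> tuple[int, float]:
    """Record count and fraction of the Lost Set a single ``[tiab]`` phrase
    retrieves."""
    lost = set(lost)
    if not lost:
        raise ValueError("lost set is empty")
    count = sum(1 for pmid in lost if match_phrase(corpus[pmid], phrase, "TIAB"))
    return count, count / len(lost)


def _coverage_map(
    candidates: Sequence[CandidateTerm | str], lost: set[str], corpus: Corpus
) -> dict[str, frozenset[str]]:
    """Coverage of each candidate phrase inside the Lost Set.  Duplicate
    phrases (case-insensitive) collapse to one entry keyed by their first
    spelling."""
    coverage: dict[str, frozenset[str]] = {}
    seen_lower: set[str] = set()
    for cand in candidates:
        phrase = cand.phrase if isinstance(cand, CandidateTerm) else cand
        if phrase.lower() in seen_lower:
            continue
        seen_lower.add(phrase.lower())
        coverage[phrase] = frozenset(
            pmid for pmid in lost if match_phrase(corpus[pmid], phrase, "TIAB")
        )
    return coverage


def greedy_select(
    candidates: Sequence[CandidateTerm | str], lost: Iterable[str], corpus: Corpus
) -> SelectionResult:
    """Greedy forward selection of the best-covering OR-combination.

    Candidates may be :class:`CandidateTerm` objects or bare phrases.
    Raises on an empty candidate list or an empty Lost Set.
    """
    lost = set(lost)
    if not candidates:
        raise ValueError("no candidates to select from")
    if not lost:
        raise ValueError("lost set is empty")

    coverage = _coverage_map(candidates, lost, corpus)
    individual = {p: len(cov) for p, cov in coverage.items()}

    selected: list[str] = []
    gains: list[int] = []
    cumulative: list[float] = []
    covered: set[str] = set()
    remaining = set(coverage)

    while remaining:
        scored = sorted(
            remaining,
            key=lambda p: (-len(coverage[p] - covered), -individual[p], p),
        )
        best = scored[0]
        gain = len(coverage[best] - covered)
        if gain == 0:
            break
        if len(scored) > 1:
            runner = scored[1]
            if len(coverage[runner] - covered) == gain:
                logger.info(
                    "tie at gain %d broken for %r over %r by (individual recall, phrase)",
                    gain, best, runner,
                )
        selected.append(best)
        gains.append(gain)
        covered |= coverage[best]
        cumulative.append(len(covered) / len(lost))
        remaining.discard(best)

    return SelectionResult(
        selected=tuple(selected),
        marginal_gains=tuple(gains),
        cumulative_recall=tuple(cumulative),
        rejected_redundant=tuple(sorted(remaining)),
        covered=frozenset(covered),
        lost_size=len(lost),
    )


def exhaustive_select(
    candidates: Sequence[CandidateTerm | str],
    lost: Iterable[str],
    corpus: Corpus,
    k: int | None = None,
    max_candidates: int = 12,
) -> tuple[tuple[str, ...], int]:
    """Best coverage over all combinations of up to *k* candidates.

    Exponential in the candidate count, so refused above *max_candidates*.
    Returns the best combination (deterministic tie-break: lexicographically
    smallest phrase tuple among maximal-coverage combinations of minimal
    size) and its coverage count.
    """
    lost = set(lost)
    coverage = _coverage_map(candidates, lost, corpus)
    phrases = sorted(coverage)
    if len(phrases) > max_candidates:
        raise ValueError(
            f"{len(phrases)} candidates exceed the exhaustive-search limit of {max_candidates}"
        )
    if k is None:
        k = len(phrases)
    best: tuple[tuple[str, ...], int] = ((), 0)
    for size in range(1, k + 1):
        for combo in combinations(phrases, size):
            count = len(frozenset().union(*(coverage[p] for p in combo)))
            if count > best[1]:
                best = (combo, count)
    return best
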