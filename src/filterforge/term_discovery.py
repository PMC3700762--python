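"""Phase 4: frequency-driven discovery of natural-language alternative terms.

Titles and abstracts of a Lost-Set subset are pooled and reduced to a
frequency-ranked list of single tokens.  Tokens on the stoplist or at or
below the frequency floor (default: raw frequency <= 10) are removed.  The
phrasal contexts of each surviving token -- all contiguous n-grams (2..5
tokens) containing it -- are expanded, and high-frequency phrases (raw
frequency >= 10) are retained.  Finally, each phrase is searched back
against its own subset: a candidate survives only if it retrieves strictly
more than the recall cutoff (default 5%) of the subset's records and is not
on the blocklist.

Note the deliberate boundary asymmetry, kept exactly as configured by the
procedure this implements: single tokens are *removed* at frequency <= 10,
phrases are *retained* at frequency >= 10.

The stoplist and blocklist replace a human review step.  The stoplist drops
tokens clearly not specific to any clinical concept (function words,
boilerplate like "patients"); the blocklist records explicit specificity or
equivalence judgments against whole phrases (e.g. rejecting an incomplete
concept such as "left ventricular", or a related-but-not-equivalent disease
name).  Both are explicit, logged inputs rather than silent automation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from filterforge.medline_corpus import Citation
from filterforge.retrieval_engine import tokenize

__all__ = [
    "DEFAULT_STOPLIST", "CandidateTerm",
    "single_term_frequencies", "apply_floors", "phrase_contexts",
    "candidate_filter", "discover_candidates",
]

# Function words plus abstract boilerplate; deliberately conservative so that
# clinically meaningful short tokens (e.g. "lv", "left") always survive.
DEFAULT_STOPLIST: frozenset[str] = frozenset("""
    a an and or not the of in on for with without to from by at as is are was
    were be been being this that these those it its we our their there than
    then but if into during after before between among per vs versus
    patients patient study studies results conclusions methods background
    objective objectives aim aims significantly significant
""".split())


@dataclass(frozen=True)
class CandidateTerm:
    """A discovered phrase and its performance inside its source subset.

    ``raw_frequency`` counts total occurrences across the subset's pooled
    titles+abstracts; ``record_occurrence`` counts distinct subset records
    matched; ``subset_recall`` is record_occurrence over subset size.
    """

    phrase: str
    raw_frequency: int
    record_occurrence: int
    subset_recall: float
    source_subset: str

    def __post_init__(self) -> None:
        if self.record_occurrence > self.raw_frequency:
            raise ValueError(f"{self.phrase!r}: record occurrence exceeds raw frequency")
        if not 0.0 <= self.subset_recall <= 1.0:
            raise ValueError(f"{self.phrase!r}: subset recall outside [0, 1]")


def _record_tokens(c: Citation) -> tuple[str, ...]:
    return tokenize(c.title) + tokenize(c.abstract)


def single_term_frequencies(
    subset: Sequence[Citation],
) -> list[tuple[str, int, int]]:
    """Frequency-ranked single tokens from pooled subset titles+abstracts.

    Returns ``(token, raw_frequency, record_occurrence)`` sorted by
    descending raw frequency, ties broken lexicographically.  Raises on an
    empty subset.
    """
    if not subset:
        raise ValueError("subset is empty")
    raw: Counter[str] = Counter()
    records: Counter[str] = Counter()
    for c in subset:
        tokens = _record_tokens(c)
        raw.update(tokens)
        records.update(set(tokens))
    return sorted(
        ((tok, raw[tok], records[tok]) for tok in raw),
        key=lambda item: (-item[1], item[0]),
    )


def apply_floors(
    ranked: Iterable[tuple[str, int, int]],
    min_frequency: int = 10,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
) -> list[tuple[str, int, int]]:
    """Drop stoplisted tokens and tokens with raw frequency <= *min_frequency*."""
    return [
        item for item in ranked
        if item[1] > min_frequency and item[0] not in stoplist
    ]


def _ngram_tables(
    subset: Sequence[Citation], max_len: int
) -> tuple[Counter[tuple[str, ...]], Counter[tuple[str, ...]]]:
    """Raw and per-record counts of all n-grams, 2 <= n <= max_len."""
    raw: Counter[tuple[str, ...]] = Counter()
    records: Counter[tuple[str, ...]] = Counter()
    for c in subset:
        seen: set[tuple[str, ...]] = set()
        # Title and abstract are windowed separately so no phrase is counted
        # across the field boundary, matching [tiab] phrase semantics.
        for tokens in (tokenize(c.title), tokenize(c.abstract)):
            for n in range(2, max_len + 1):
                for i in range(len(tokens) - n + 1):
                    gram = tokens[i:i + n]
                    raw[gram] += 1
                    seen.add(gram)
        records.update(seen)
    return raw, records


def phrase_contexts(
    subset: Sequence[Citation],
    seed_token: str,
    min_frequency: int = 10,
    max_len: int = 5,
) -> list[tuple[str, int, int]]:
    """All contiguous n-grams (2..max_len tokens) containing *seed_token*
    with raw frequency >= *min_frequency* across the subset.

    Overlapping phrases of different specificity are all returned;
    selecting among them is the caller's concern (greedy selection resolves
    exact-coverage duplicates, the blocklist records human judgments).
    """
    raw, records = _ngram_tables(subset, max_len)
    out = [
        (" ".join(gram), count, records[gram])
        for gram, count in raw.items()
        if seed_token in gram and count >= min_frequency
    ]
    return sorted(out, key=lambda item: (-item[1], item[0]))


def candidate_filter(
    phrases: Iterable[tuple[str, int, int]],
    subset: Sequence[Citation],
    recall_cutoff: float = 0.05,
    blocklist: frozenset[str] | set[str] = frozenset(),
    source_subset: str = "",
) -> list[CandidateTerm]:
    """Keep phrases retrieving strictly more than *recall_cutoff* of their
    own subset and not on the blocklist."""
    size = len(subset)
    if size == 0:
        raise ValueError("subset is empty")
    blocked = {b.lower() for b in blocklist}
    kept = []
    for phrase, raw_frequency, record_occurrence in phrases:
        recall = record_occurrence / size
        if recall > recall_cutoff and phrase.lower() not in blocked:
            kept.append(
                CandidateTerm(
                    phrase=phrase,
                    raw_frequency=raw_frequency,
                    record_occurrence=record_occurrence,
                    subset_recall=recall,
                    source_subset=source_subset,
                )
            )
    return sorted(kept, key=lambda t: (-t.record_occurrence, t.phrase))


def discover_candidates(
    subset: Sequence[Citation],
    source_subset: str = "",
    min_frequency: int = 10,
    recall_cutoff: float = 0.05,
    max_len: int = 5,
    stoplist: frozenset[str] | set[str] = DEFAULT_STOPLIST,
    blocklist: frozenset[str] | set[str] = frozenset(),
) -> list[CandidateTerm]:
    """Full Phase-4 analysis of one subset.

    Equivalent to running :func:`single_term_frequencies`,
    :func:`apply_floors`, :func:`phrase_contexts` for every surviving token
    and :func:`candidate_filter` on the pooled phrases, but the n-gram
    table is built once per subset.  An empty subset yields no candidates.
    """
    if not subset:
        return []
    singles = apply_floors(
        single_term_frequencies(subset), min_frequency=min_frequency, stoplist=stoplist
    )
    surviving = {tok for tok, _, _ in singles}
    if not surviving:
        return []
    raw, records = _ngram_tables(subset, max_len)
    phrases = [
        (" ".join(gram), count, records[gram])
        for gram, count in raw.items()
        if count >= min_frequency and any(tok in surviving for tok in gram)
    ]
    return candidate_filter(
        phrases, subset,
        recall_cutoff=recall_cutoff, blocklist=blocklist, source_subset=source_subset,
    )
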