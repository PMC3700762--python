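"""Synthetic MEDLINE corpora with controlled MeSH/textword concordance.

The generator stands in for a live bibliographic database.  Each record is
assigned to at most one *concept* (a MeSH heading with a canonical
natural-language phrase).  For an indexed (MEDLINE-status) record about a
concept, the heading is assigned with probability ``p_mesh``; given the
heading, the canonical phrase appears in the title or abstract with
probability ``p_phrase_given_mesh``, and when it does not, each alternative
phrase appears independently with its own conditional probability.  This
reproduces the phenomenon the pipeline measures: indexers see beyond
titles and abstracts, so a fraction of indexed records is retrievable by
MeSH but not by the same string as a textword, and that fraction carries
the planted alternative vocabulary.

Non-indexed records (Publisher/In-Process status) never carry headings but
receive phrases under the same conditional scheme, emulating not-yet-indexed
content.  Everything else in a title or abstract is background vocabulary:
uniform draws from a synthetic token pool, so phrase matches never arise by
accident.  Phrases are embedded as intact token runs (never split), because
retrieval matching is adjacency-based; they are inserted at chunk
boundaries so that one phrase can never interrupt another.

Generation is fully deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from filterforge.medline_corpus import Citation, Corpus, Status
from filterforge.lost_set_pipeline import StudyLimits, SubsetLimit
from filterforge.retrieval_engine import tokenize

__all__ = [
    "ConceptSpec", "CorpusSpec", "generate",
    "PlantedAlternative", "planted_truth", "expected_lost_fraction",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ConceptSpec:
    """One MeSH concept with its canonical phrase and planted alternatives.

    ``weight`` is the fraction of corpus records about the concept (concept
    assignment is mutually exclusive across concepts).  ``alternatives``
    maps phrases to their probability of appearing given that the record is
    indexed with the heading but lacks the canonical phrase -- i.e. their
    conditional frequency inside the concept's Lost-Set subset.
    """

    mesh_heading: str
    canonical_phrase: str
    weight: float
    p_mesh: float = 1.0
    p_phrase_given_mesh: float = 0.88
    alternatives: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        _check_prob("weight", self.weight)
        _check_prob("p_mesh", self.p_mesh)
        _check_prob("p_phrase_given_mesh", self.p_phrase_given_mesh)
        canon = self.canonical_phrase.lower()
        for phrase, p in self.alternatives:
            _check_prob(f"p({phrase!r})", p)
            if phrase.lower() == canon:
                raise ValueError(f"alternative {phrase!r} duplicates the canonical phrase")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus; same seed, same corpus, always."""

    n_records: int = 3000
    fraction_indexed: float = 0.9
    concepts: tuple[ConceptSpec, ...] = ()
    background_vocab_size: int = 400
    abstract_token_range: tuple[int, int] = (80, 250)
    title_token_range: tuple[int, int] = (5, 15)
    p_no_abstract: float = 0.02
    p_title_placement: float = 0.15
    in_process_fraction: float = 0.2          # of the non-indexed remainder
    language_pool: tuple[tuple[str, float], ...] = (("eng", 0.98), ("fre", 0.02))
    year_pool: tuple[tuple[int, float], ...] = ((2010, 0.97), (2009, 0.03))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        _check_prob("fraction_indexed", self.fraction_indexed)
        _check_prob("p_no_abstract", self.p_no_abstract)
        _check_prob("p_title_placement", self.p_title_placement)
        _check_prob("in_process_fraction", self.in_process_fraction)
        total_weight = sum(c.weight for c in self.concepts)
        if total_weight > 1.0 + 1e-9:
            raise ValueError(f"concept weights sum to {total_weight} > 1")
        for pool_name, pool in (("language_pool", self.language_pool),
                                ("year_pool", self.year_pool)):
            share = sum(p for _, p in pool)
            if not math.isclose(share, 1.0, abs_tol=1e-9):
                raise ValueError(f"{pool_name} probabilities sum to {share}, not 1")


def _pick(rng: np.random.Generator, pool: tuple[tuple[object, float], ...]) -> object:
    u = rng.random()
    acc = 0.0
    for value, p in pool:
        acc += p
        if u < acc:
            return value
    return pool[-1][0]


def generate(spec: CorpusSpec) -> Corpus:
    """Generate a corpus from *spec*, deterministically for its seed."""
    rng = np.random.default_rng(spec.seed)
    pool = [f"w{i:03d}" for i in range(spec.background_vocab_size)]
    concept_pool = tuple((c, c.weight) for c in spec.concepts)
    none_weight = 1.0 - sum(c.weight for c in spec.concepts)

    citations = []
    for i in range(spec.n_records):
        pmid = str(10_000_000 + i)

        if rng.random() < spec.fraction_indexed:
            status = Status.MEDLINE
        elif rng.random() < spec.in_process_fraction:
            status = Status.IN_PROCESS
        else:
            status = Status.PUBLISHER

        concept: ConceptSpec | None = None
        u = rng.random()
        acc = none_weight
        for c in spec.concepts:
            if u >= acc and u < acc + c.weight:
                concept = c
                break
            acc += c.weight

        headings: tuple[str, ...] = ()
        phrases: list[str] = []
        if concept is not None and rng.random() < concept.p_mesh:
            if status is Status.MEDLINE:
                headings = (concept.mesh_heading,)
            if rng.random() < concept.p_phrase_given_mesh:
                phrases.append(concept.canonical_phrase)
            else:
                for phrase, p in concept.alternatives:
                    if rng.random() < p:
                        phrases.append(phrase)

        language = str(_pick(rng, spec.language_pool))
        year = int(_pick(rng, spec.year_pool))  # type: ignore[arg-type]
        has_abstract = rng.random() >= spec.p_no_abstract

        lo, hi = spec.title_token_range
        title_chunks = [[pool[j]] for j in rng.integers(0, len(pool), int(rng.integers(lo, hi + 1)))]
        abstract_chunks: list[list[str]] = []
        if has_abstract:
            lo, hi = spec.abstract_token_range
            abstract_chunks = [
                [pool[j]] for j in rng.integers(0, len(pool), int(rng.integers(lo, hi + 1)))
            ]

        for phrase in phrases:
            in_title = (not has_abstract) or rng.random() < spec.p_title_placement
            chunks = title_chunks if in_title else abstract_chunks
            idx = int(rng.integers(0, len(chunks) + 1))
            chunks.insert(idx, list(tokenize(phrase)))

        title = " ".join(tok for chunk in title_chunks for tok in chunk)
        abstract = " ".join(tok for chunk in abstract_chunks for tok in chunk)

        citations.append(
            Citation(
                pmid=pmid, title=title, abstract=abstract,
                mesh_headings=headings, language=language,
                pub_year=year, status=status,
            )
        )
    return Corpus(citations)


# ---------------------------------------------------------------------------
# Planted ground truth


def _limit_attrition(spec: CorpusSpec, limits: StudyLimits) -> float:
    """Probability a record survives the language/year/abstract limits."""
    factor = 1.0
    if limits.language:
        factor *= sum(p for lang, p in spec.language_pool
                      if _lang(lang) == _lang(limits.language))
    if limits.pub_year is not None:
        factor *= sum(p for year, p in spec.year_pool if year == limits.pub_year)
    if limits.require_abstract:
        factor *= 1.0 - spec.p_no_abstract
    return factor


def _lang(value: str) -> str:
    from filterforge.retrieval_engine import _lang_canon
    return _lang_canon(value)


@dataclass(frozen=True)
class PlantedAlternative:
    """Expected discovery outcome of one planted alternative phrase.

    ``classification`` is three-valued: ``recoverable`` when the expected
    record occurrence clears the phrase-frequency floor and the expected
    recall clears the subset-recall cutoff, each by a z-scaled binomial
    margin; ``unrecoverable`` when either expectation falls below its
    threshold by the same margin; ``borderline`` when a threshold lies
    within sampling noise of the expectation, so a finite corpus cannot
    decide it reliably.
    """

    concept: str
    phrase: str
    planted_rate: float
    expected_subset_size: float
    expected_record_occurrence: float
    expected_subset_recall: float
    classification: str


def expected_lost_fraction(spec: CorpusSpec) -> float:
    """Expected |lost| / |#1|: the weighted share of MeSH-retrieved records
    whose canonical phrase is absent.  Independent of study limits, which
    remove records uniformly."""
    num = sum(c.weight * c.p_mesh * (1.0 - c.p_phrase_given_mesh) for c in spec.concepts)
    den = sum(c.weight * c.p_mesh for c in spec.concepts)
    return num / den if den else 0.0


def planted_truth(
    spec: CorpusSpec,
    limits: StudyLimits = StudyLimits(),
    min_frequency: int = 10,
    recall_cutoff: float = 0.05,
    z: float = 2.326,
) -> list[PlantedAlternative]:
    """Expected candidate table for the planted alternatives.

    Each record embeds a phrase at most once, so the expected raw frequency
    of an alternative equals its expected record occurrence; the phrase
    floor is assessed on that common value.  ``z`` (default: the one-sided
    99% normal quantile) sets the margin separating decidable from
    borderline alternatives.
    """
    attrition = _limit_attrition(spec, limits)
    if limits.subset is SubsetLimit.NOT_MEDLINE:
        raise ValueError("lost-set analysis requires the indexed subset")
    out: list[PlantedAlternative] = []
    for c in spec.concepts:
        subset = (
            spec.n_records * spec.fraction_indexed * c.weight
            * c.p_mesh * (1.0 - c.p_phrase_given_mesh) * attrition
        )
        for phrase, p in c.alternatives:
            occ = subset * p
            if subset < 1.0:
                cls = "unrecoverable"
            else:
                sd_occ = math.sqrt(subset * p * (1.0 - p))
                sd_recall = math.sqrt(p * (1.0 - p) / subset)
                occ_ok = occ >= min_frequency + z * sd_occ
                occ_bad = occ <= min_frequency - z * sd_occ
                recall_ok = p > recall_cutoff + z * sd_recall
                recall_bad = p <= recall_cutoff - z * sd_recall
                if occ_ok and recall_ok:
                    cls = "recoverable"
                elif occ_bad or recall_bad:
                    cls = "unrecoverable"
                else:
                    cls = "borderline"
            out.append(
                PlantedAlternative(
                    concept=c.mesh_heading,
                    phrase=phrase,
                    planted_rate=p,
                    expected_subset_size=subset,
                    expected_record_occurrence=occ,
                    expected_subset_recall=p,
                    classification=cls,
                )
            )
    return out
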