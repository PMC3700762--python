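"""Synthetic corpus generator: determinism, planted limits, and the
binomial calibration of planted rates."""

import io

import pytest
from scipy.stats import binom

from filterforge import heart_failure as hf
from filterforge.medline_corpus import Status, write_medline
from filterforge.query_model import parse_pubmed
from filterforge.lost_set_pipeline import StudyLimits, compute_lost_set
from filterforge.greedy_selection import term_recall
from filterforge.synthetic_corpus import (
    ConceptSpec, CorpusSpec, expected_lost_fraction, generate, planted_truth,
)


def _single_concept_spec(p_mesh=1.0, p_phrase=0.88, alternatives=(), **kwargs):
    concept = ConceptSpec(
        mesh_heading="Heart Failure",
        canonical_phrase="heart failure",
        weight=1.0,
        p_mesh=p_mesh,
        p_phrase_given_mesh=p_phrase,
        alternatives=alternatives,
    )
    defaults = dict(
        n_records=400, fraction_indexed=1.0, concepts=(concept,),
        p_no_abstract=0.0, language_pool=(("eng", 1.0),), year_pool=((2010, 1.0),),
        seed=5,
    )
    defaults.update(kwargs)
    return CorpusSpec(**defaults)


FILTER = parse_pubmed("heart failure[tw]")
NO_LIMITS = StudyLimits.none()


def test_same_seed_gives_byte_identical_corpus():
    spec = _single_concept_spec(n_records=150)
    first, second = io.StringIO(), io.StringIO()
    write_medline(generate(spec), first)
    write_medline(generate(spec), second)
    assert first.getvalue() == second.getvalue()
    assert generate(spec) == generate(spec)


def test_different_seed_changes_corpus():
    a = generate(_single_concept_spec(seed=1))
    b = generate(_single_concept_spec(seed=2))
    assert a != b


def test_concordant_limit_yields_empty_lost_set():
    corpus = generate(_single_concept_spec(p_phrase=1.0))
    ls = compute_lost_set(FILTER, corpus, NO_LIMITS)
    assert ls.lost == frozenset()


def test_discordant_limit_loses_everything_and_alternative_recalls_fully():
    spec = _single_concept_spec(p_phrase=0.0, alternatives=(("cardiac failure", 1.0),))
    corpus = generate(spec)
    ls = compute_lost_set(FILTER, corpus, NO_LIMITS)
    mesh_only = {c.pmid for c in corpus if c.mesh_headings}
    assert ls.lost == ls.mesh_retrieved == mesh_only
    count, fraction = term_recall("cardiac failure", ls.subsets["heart failure"], corpus)
    assert fraction == 1.0


def test_unindexed_records_carry_phrases_but_no_headings():
    spec = _single_concept_spec(p_phrase=1.0, fraction_indexed=0.5, n_records=300)
    corpus = generate(spec)
    unindexed = [c for c in corpus if c.status is not Status.MEDLINE]
    assert unindexed
    assert all(not c.mesh_headings for c in unindexed)
    assert any("heart failure" in c.title + " " + c.abstract for c in unindexed)


def test_phrases_are_embedded_as_intact_token_runs():
    spec = _single_concept_spec(
        p_phrase=0.0,
        alternatives=(("cardiac failure", 1.0), ("left ventricular systolic dysfunction", 1.0)),
        n_records=100,
    )
    corpus = generate(spec)
    lost = compute_lost_set(FILTER, corpus, NO_LIMITS).lost
    for pmid in lost:
        text = corpus[pmid].title + " " + corpus[pmid].abstract
        assert "cardiac failure" in text
        assert "left ventricular systolic dysfunction" in text


def test_lost_fraction_and_alternative_rate_within_binomial_ci():
    """At n=3000, p_mesh=0.5, canonical rate 0.88 and one alternative at
    0.095, the measured lost fraction must sit inside a 99% binomial CI of
    12% and the alternative's subset recall inside a CI of 9.5%."""
    spec = _single_concept_spec(
        n_records=3000, p_mesh=0.5, p_phrase=0.88,
        alternatives=(("cardiac failure", 0.095),), seed=12,
    )
    assert expected_lost_fraction(spec) == pytest.approx(0.12)
    corpus = generate(spec)
    ls = compute_lost_set(FILTER, corpus, NO_LIMITS)
    n1 = len(ls.mesh_retrieved)
    lo, hi = binom.interval(0.99, n1, 0.12)
    assert lo <= len(ls.lost) <= hi

    subset = ls.subsets["heart failure"]
    count, _ = term_recall("cardiac failure", subset, corpus)
    lo, hi = binom.interval(0.99, len(subset), 0.095)
    assert lo <= count <= hi


class TestPlantedTruth:
    def test_rare_alternative_flagged_unrecoverable(self):
        spec = _single_concept_spec(
            p_phrase=0.0, alternatives=(("rare phrase", 0.002),), n_records=400,
        )
        (alt,) = planted_truth(spec, StudyLimits.none())
        assert alt.expected_subset_size == pytest.approx(400)
        assert alt.expected_record_occurrence == pytest.approx(0.8)
        assert alt.classification == "unrecoverable"

    def test_common_alternative_flagged_recoverable(self):
        spec = _single_concept_spec(
            p_phrase=0.0, alternatives=(("common phrase", 0.2),), n_records=400,
        )
        (alt,) = planted_truth(spec, StudyLimits.none())
        assert alt.expected_record_occurrence == pytest.approx(80)
        assert alt.classification == "recoverable"

    def test_regime_classifications_are_stable_inputs(self):
        classes = {
            alt.phrase: alt.classification
            for alt in planted_truth(hf.heart_failure_regime(seed=0), hf.STUDY_LIMITS)
        }
        assert classes["cardiac failure"] == "recoverable"
        assert classes["cardiac resynchronization"] == "borderline"
        assert classes["lv dysfunction"] == "unrecoverable"
        assert classes["left ventricular diastolic dysfunction"] == "unrecoverable"
        assert classes["chagas disease"] == "unrecoverable"


class TestValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ConceptSpec("H", "h", weight=1.2)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ConceptSpec("H", "h", weight=0.5, p_mesh=-0.1)

    def test_alternative_must_differ_from_canonical(self):
        with pytest.raises(ValueError, match="duplicates the canonical"):
            ConceptSpec("H", "heart failure", weight=0.5,
                        alternatives=(("Heart Failure", 0.1),))

    def test_weights_cannot_exceed_one(self):
        c = ConceptSpec("H", "h", weight=0.6)
        d = ConceptSpec("G", "g", weight=0.6)
        with pytest.raises(ValueError, match="> 1"):
            CorpusSpec(concepts=(c, d))
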