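"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: boolean
queries are re-evaluated per citation by truth-table recursion, phrase
matching by string containment over space-joined tokens, and random query
ASTs / corpora are built directly from primitives.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from filterforge.medline_corpus import Citation, Corpus, Status
from filterforge.query_model import And, FieldTag, Not, Or, Query, Term
from filterforge import heart_failure as hf

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Brute-force oracles


def split_tokens(text: str) -> list[str]:
    """Token oracle: lowercase, keep alphanumeric runs."""
    out, cur = [], []
    for ch in text.lower():
        if ch.isascii() and (ch.isalpha() or ch.isdigit()):
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def phrase_in_field(text: str, phrase: str) -> bool:
    """String-containment phrase oracle over space-joined tokens."""
    hay = " " + " ".join(split_tokens(text)) + " "
    needle = " " + " ".join(split_tokens(phrase)) + " "
    return needle in hay


def heading_tokens(heading: str) -> tuple[str, ...]:
    parts = heading.split(",")
    if len(parts) == 2 and parts[0].strip() and parts[1].strip():
        heading = parts[1].strip() + " " + parts[0].strip()
    return tuple(split_tokens(heading))


def citation_matches(q: Query, c: Citation) -> bool:
    """Truth-table evaluation of a query for one citation."""
    if isinstance(q, And):
        return all(citation_matches(child, c) for child in q.children)
    if isinstance(q, Or):
        return any(citation_matches(child, c) for child in q.children)
    if isinstance(q, Not):
        return citation_matches(q.left, c) and not citation_matches(q.right, c)
    assert isinstance(q, Term)
    tag = q.tag
    if tag is FieldTag.TIAB:
        return phrase_in_field(c.title, q.text) or phrase_in_field(c.abstract, q.text)
    if tag is FieldTag.MH_NOEXP:
        return any(heading_tokens(h) == heading_tokens(q.text) for h in c.mesh_headings)
    if tag is FieldTag.TW:
        return citation_matches(Term(q.text, FieldTag.TIAB), c) or citation_matches(
            Term(q.text, FieldTag.MH_NOEXP), c
        )
    if tag is FieldTag.LA:
        alias = {"english": "eng", "french": "fre"}
        canon = lambda v: alias.get(v.lower(), v.lower())
        return canon(c.language) == canon(q.text)
    if tag is FieldTag.DP:
        return c.pub_year == int(q.text)
    if tag is FieldTag.SB:
        return c.status is Status.MEDLINE
    if tag is FieldTag.HASABSTRACT:
        return bool(c.abstract.strip())
    raise AssertionError(tag)


def evaluate_bruteforce(q: Query, corpus: Corpus) -> set[str]:
    return {c.pmid for c in corpus if citation_matches(q, c)}


# ---------------------------------------------------------------------------
# Random instances


VOCAB = ["heart", "failure", "cardiac", "ventricular", "dysfunction",
         "lv", "output", "ejection", "fraction", "muscle"]
HEADINGS = ["Heart Failure", "Ventricular Dysfunction, Left", "Cardiomyopathy"]


def random_citation(rng: random.Random, pmid: str) -> Citation:
    status = rng.choice([Status.MEDLINE] * 3 + [Status.PUBLISHER, Status.IN_PROCESS])
    headings = ()
    if status is Status.MEDLINE and rng.random() < 0.6:
        headings = tuple(rng.sample(HEADINGS, rng.randint(1, 2)))
    return Citation(
        pmid=pmid,
        title=" ".join(rng.choices(VOCAB, k=rng.randint(2, 6))),
        abstract=" ".join(rng.choices(VOCAB, k=rng.randint(0, 25))),
        mesh_headings=headings,
        language=rng.choice(["eng", "fre", "English"]),
        pub_year=rng.choice([2009, 2010, 2011]),
        status=status,
    )


def random_corpus(rng: random.Random, n: int) -> Corpus:
    return Corpus(random_citation(rng, str(5_000_000 + i)) for i in range(n))


def random_query(rng: random.Random, depth: int) -> Query:
    if depth == 0 or rng.random() < 0.4:
        kind = rng.random()
        if kind < 0.5:
            phrase = " ".join(rng.sample(VOCAB, rng.randint(1, 3)))
            tag = rng.choice([FieldTag.TW, FieldTag.TIAB])
            return Term(phrase, tag)
        if kind < 0.7:
            return Term(rng.choice(HEADINGS), FieldTag.MH_NOEXP)
        limit = rng.random()
        if limit < 0.3:
            return Term(rng.choice(["English", "eng", "fre"]), FieldTag.LA)
        if limit < 0.6:
            return Term(str(rng.choice([2009, 2010])), FieldTag.DP)
        if limit < 0.8:
            return Term("Medline", FieldTag.SB)
        return Term("", FieldTag.HASABSTRACT)
    op = rng.random()
    if op < 0.4:
        return Or(tuple(random_query(rng, depth - 1) for _ in range(rng.randint(2, 3))))
    if op < 0.8:
        return And(tuple(random_query(rng, depth - 1) for _ in range(rng.randint(2, 3))))
    return Not(random_query(rng, depth - 1), random_query(rng, depth - 1))


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def regime_corpus():
    """One heart-failure-regime synthetic corpus, shared read-only across tests."""
    from filterforge.synthetic_corpus import generate

    return generate(hf.heart_failure_regime(seed=7))


@pytest.fixture
def toy_corpus() -> Corpus:
    """Small handcrafted corpus exercising every field the engine reads."""
    return Corpus([
        Citation(pmid="1", title="Cardiac resynchronization therapy outcomes",
                 abstract="Outcomes of cardiac failure management in adults.",
                 mesh_headings=("Heart Failure",), language="eng",
                 pub_year=2010, status=Status.MEDLINE),
        Citation(pmid="2", title="Dysfunction of the left ventricular wall",
                 abstract="dysfunction of the left ventricular wall studied",
                 mesh_headings=("Ventricular Dysfunction, Left",), language="eng",
                 pub_year=2010, status=Status.MEDLINE),
        Citation(pmid="3", title="Heart failure review",
                 abstract="A review of heart failure therapy.",
                 mesh_headings=("Heart Failure", "Cardiomyopathy"), language="eng",
                 pub_year=2010, status=Status.MEDLINE),
        Citation(pmid="4", title="Emerging left ventricular dysfunction markers",
                 abstract="left ventricular dysfunction biomarkers ahead of print",
                 mesh_headings=(), language="eng",
                 pub_year=2010, status=Status.PUBLISHER),
        Citation(pmid="5", title="Une revue cardiologique",
                 abstract="resume en francais",
                 mesh_headings=("Heart Failure",), language="fre",
                 pub_year=2009, status=Status.MEDLINE),
        Citation(pmid="6", title="No abstract heart failure note",
                 abstract="", mesh_headings=("Heart Failure",), language="eng",
                 pub_year=2010, status=Status.MEDLINE),
    ])
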