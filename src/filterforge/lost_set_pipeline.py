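"""Phases 1-3 of the pipeline: isolate the Lost Set and its per-term subsets.

Search #1 runs the translated filter with its terms acting on MeSH and
textword fields (``[tw]``/``[mh:noexp]``); search #2 reruns it with every
term retagged to ``[tiab]``; the Lost Set is ``#1 NOT #2`` -- citations
retrievable only through their MeSH indexing.  Both searches carry the same
study limits (language, publication year, has-abstract, subset status).

The Lost Set is then partitioned into one subset per filter term that has a
MeSH interpretation: the citations indexed with that heading whose
titles/abstracts lack the corresponding natural-order phrase.  Subsets may
overlap (a citation indexed with two filter headings and containing neither
phrase belongs to both) and are never forced to be disjoint.  Terms with no
MeSH interpretation get no subset: their retrieval is unaffected by the
``[tw]`` to ``[tiab]`` conversion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from filterforge.medline_corpus import Corpus
from filterforge.query_model import (
    And, FieldTag, Not, Or, Query, Term, invert_heading, retag,
)
from filterforge.retrieval_engine import (
    evaluate, match_mesh, match_phrase, normalize_heading,
)

__all__ = ["SubsetLimit", "StudyLimits", "LostSet", "compute_lost_set", "apply_limits"]


class SubsetLimit(enum.Enum):
    MEDLINE_ONLY = "medline"
    NOT_MEDLINE = "not-medline"
    ALL = "all"


@dataclass(frozen=True)
class StudyLimits:
    """Limits applied identically to searches #1 and #2."""

    language: str | None = "English"
    pub_year: int | None = 2010
    require_abstract: bool = True
    subset: SubsetLimit = SubsetLimit.MEDLINE_ONLY

    def limit_terms(self) -> list[Term]:
        terms: list[Term] = []
        if self.language:
            terms.append(Term(self.language, FieldTag.LA))
        if self.pub_year is not None:
            terms.append(Term(str(self.pub_year), FieldTag.DP))
        if self.require_abstract:
            terms.append(Term("", FieldTag.HASABSTRACT))
        if self.subset is SubsetLimit.MEDLINE_ONLY:
            terms.append(Term("Medline", FieldTag.SB))
        return terms

    @classmethod
    def none(cls) -> "StudyLimits":
        return cls(language=None, pub_year=None, require_abstract=False, subset=SubsetLimit.ALL)


def apply_limits(q: Query, limits: StudyLimits) -> Query:
    """AND the limit terms onto a query (NOT-wrapping for the non-Medline
    subset); with no active limits the query is returned unchanged."""
    terms = limits.limit_terms()
    base: Query = And((q, *terms)) if terms else q
    if limits.subset is SubsetLimit.NOT_MEDLINE:
        base = Not(base, Term("Medline", FieldTag.SB))
    return base


@dataclass(frozen=True)
class LostSet:
    """The three retrieval sets plus per-MeSH-term subsets of the Lost Set.

    ``lost == mesh_retrieved - tiab_retrieved`` by construction; every
    subset is contained in ``lost``.  ``overlap`` reports ``#1 & #2``
    explicitly because containment of #2 in #1 is not guaranteed once an
    ``[mh:noexp]`` term is present.
    """

    mesh_retrieved: frozenset[str]              # search #1
    tiab_retrieved: frozenset[str]              # search #2
    lost: frozenset[str]                        # search #3 = #1 NOT #2
    subsets: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def overlap(self) -> frozenset[str]:
        return self.mesh_retrieved & self.tiab_retrieved

    @property
    def lost_fraction(self) -> float:
        """|lost| / |#1|; 0.0 for an empty #1."""
        return len(self.lost) / len(self.mesh_retrieved) if self.mesh_retrieved else 0.0


def _mesh_interpretable(term: Term, corpus: Corpus) -> bool:
    """A term has a MeSH interpretation if it is MH-tagged, or if its text
    matches some normalized heading assigned anywhere in the corpus."""
    if term.tag is FieldTag.MH_NOEXP:
        return True
    target = normalize_heading(term.text)
    return any(
        normalize_heading(h) == target
        for c in corpus for h in c.mesh_headings
    )


def compute_lost_set(filter_q: Query, corpus: Corpus, limits: StudyLimits) -> LostSet:
    """Run searches #1-#3 and partition the Lost Set per MeSH-bearing term.

    *filter_q* must use ``[tw]``/``[mh:noexp]`` tags only; a filter already
    containing ``[tiab]`` tags indicates phase mixing and is rejected.
    """
    leaves = list(filter_q.leaves())
    for leaf in leaves:
        if not isinstance(leaf, Term) or leaf.tag not in (FieldTag.TW, FieldTag.MH_NOEXP):
            raise ValueError(
                f"filter must use [tw]/[mh:noexp] tags only, found {leaf!r}"
            )

    s1 = frozenset(evaluate(apply_limits(filter_q, limits), corpus))
    s2 = frozenset(evaluate(apply_limits(retag(filter_q, FieldTag.TIAB), limits), corpus))
    lost = s1 - s2

    subsets: dict[str, frozenset[str]] = {}
    for leaf in leaves:
        assert isinstance(leaf, Term)
        if not _mesh_interpretable(leaf, corpus):
            continue
        phrase = invert_heading(leaf.text)
        members = frozenset(
            pmid for pmid in lost
            if match_mesh(corpus[pmid], leaf.text)
            and not match_phrase(corpus[pmid], phrase, "TIAB")
        )
        subsets[leaf.text] = members

    return LostSet(
        mesh_retrieved=s1, tiab_retrieved=s2, lost=lost, subsets=subsets,
    )
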