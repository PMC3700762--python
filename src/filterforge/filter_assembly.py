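"""Assemble the final two-branch PubMed filter.

The extended filter is the OR of two complementary branches:

* the **validated branch** -- the original translation, restricted to the
  indexed subset (``AND Medline[sb]``), so its known retrieval behavior in
  indexed content is untouched;
* the **supplementary branch** -- the original terms retagged to
  ``[tiab]``, OR the greedy-selected natural-language terms, restricted to
  the non-indexed remainder (``NOT Medline[sb]``).

Because the subset restrictions are complementary, the branches retrieve
disjoint sets, and adding the supplementary branch can never change what
the validated filter retrieves from indexed content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from filterforge.greedy_selection import SelectionResult
from filterforge.query_model import (
    And, FieldTag, Not, Or, Query, Term, render_pubmed, retag,
)

logger = logging.getLogger(__name__)

__all__ = ["ExtendedFilter", "assemble"]


@dataclass(frozen=True)
class ExtendedFilter:
    validated_branch: Query
    supplementary_branch: Query
    combined: Query

    def render(self) -> str:
        return render_pubmed(self.combined)


def assemble(
    validated: Query, selection: SelectionResult | Sequence[str]
) -> ExtendedFilter:
    """Build the extended filter from the validated translation and the
    selected supplementary terms.

    *validated* must use ``[tw]``/``[mh:noexp]`` tags.  Retagged original
    terms precede selected terms in the supplementary branch, in original
    order; a selected term duplicating an original (case-insensitive exact
    phrase) is dropped with a warning.
    """
    for leaf in validated.leaves():
        if not isinstance(leaf, Term) or leaf.tag not in (FieldTag.TW, FieldTag.MH_NOEXP):
            raise ValueError(f"validated filter must use [tw]/[mh:noexp] tags, found {leaf!r}")

    medline_sb = Term("Medline", FieldTag.SB)
    validated_branch = And((validated, medline_sb))

    retagged = retag(validated, FieldTag.TIAB)
    if isinstance(retagged, Or):
        supplementary_terms: list[Query] = list(retagged.children)
    else:
        supplementary_terms = [retagged]

    existing = {
        leaf.text.lower()
        for node in supplementary_terms
        for leaf in node.leaves()
        if isinstance(leaf, Term)
    }
    phrases = selection.selected if isinstance(selection, SelectionResult) else selection
    for phrase in phrases:
        if phrase.lower() in existing:
            logger.warning("selected term %r duplicates an original filter term; dropped", phrase)
            continue
        existing.add(phrase.lower())
        supplementary_terms.append(Term(phrase, FieldTag.TIAB))

    supplementary_or: Query = (
        supplementary_terms[0] if len(supplementary_terms) == 1
        else Or(tuple(supplementary_terms))
    )
    supplementary_branch = Not(supplementary_or, medline_sb)

    combined = Or((validated_branch, supplementary_branch))
    return ExtendedFilter(
        validated_branch=validated_branch,
        supplementary_branch=supplementary_branch,
        combined=combined,
    )
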