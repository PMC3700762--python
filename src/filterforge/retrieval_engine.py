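"""Evaluate field-tagged boolean queries against a corpus.

The engine emulates the slice of PubMed semantics the pipeline relies on:

* ``[tiab]`` -- a phrase matches iff its tokens occur as a contiguous run
  in the title or abstract token sequence (PubMed double-quoted phrase
  searching; adjacency is required, so ``left ventricular dysfunction``
  does not match ``dysfunction of the left ventricle``);
* ``[mh:noexp]`` -- equality against an assigned MeSH descriptor after
  case folding and inverted-form normalization, never tree explosion;
* ``[tw]`` -- the union of the two (title, abstract, or MeSH descriptor).
  Real PubMed ``[tw]`` covers further fields (substance names, etc.); the
  pipeline depends only on the three modeled here, and this simplification
  is deliberate;
* limits -- ``[la]`` (with English/eng aliasing), ``[dp]`` (year equality),
  ``Medline[sb]`` (indexing status), ``"hasabstract"``;
* ``AND``/``OR``/``NOT`` as set intersection/union/difference.  ``NOT`` is
  relative complement within the corpus, never a global negation.

No automatic term mapping, stemming, stopword dropping, or truncation is
performed at match time.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Literal

from filterforge.medline_corpus import Citation, Corpus, Status
from filterforge.query_model import (
    And, FieldTag, Not, Or, Query, Term, invert_heading,
)

__all__ = [
    "tokenize", "match_phrase", "match_mesh", "evaluate",
    "normalize_heading", "UnsupportedSubsetError",
]

_SPLIT_RE = re.compile(r"[^a-z0-9]+")


@lru_cache(maxsize=131072)
def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase and split on any non-alphanumeric character, dropping
    empty fragments.  Idempotent on its own space-joined output."""
    return tuple(t for t in _SPLIT_RE.split(text.lower()) if t)


def _contains_run(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    first = needle[0]
    return any(
        haystack[i] == first and haystack[i:i + n] == needle
        for i in range(len(haystack) - n + 1)
    )


Field = Literal["TITLE", "ABSTRACT", "TIAB"]


def match_phrase(citation: Citation, phrase: str, field: Field = "TIAB") -> bool:
    """True iff the phrase's tokens occur contiguously in the given field
    (``TIAB`` = title or abstract)."""
    if not phrase:
        raise ValueError("phrase must be nonempty")
    needle = tokenize(phrase)
    if field in ("TITLE", "TIAB") and _contains_run(tokenize(citation.title), needle):
        return True
    if field in ("ABSTRACT", "TIAB") and _contains_run(tokenize(citation.abstract), needle):
        return True
    return False


@lru_cache(maxsize=65536)
def normalize_heading(heading: str) -> tuple[str, ...]:
    """Canonical token form of a MeSH heading: inverted forms (``X, Y`` with
    a single comma) are read in natural word order (``Y X``), then tokenized.
    The form is a fixed point: normalizing a space-joined normal form is a
    no-op."""
    return tokenize(invert_heading(heading))


def match_mesh(citation: Citation, heading: str) -> bool:
    """True iff *heading* equals one of the citation's MeSH descriptors after
    normalization on both sides.  No tree explosion."""
    if not heading:
        raise ValueError("heading must be nonempty")
    target = normalize_heading(heading)
    return any(normalize_heading(h) == target for h in citation.mesh_headings)


class UnsupportedSubsetError(ValueError):
    """Raised for ``[sb]`` values other than the Medline subset."""


_LANG_ALIASES = {"english": "eng", "french": "fre", "german": "ger", "spanish": "spa"}


def _lang_canon(value: str) -> str:
    v = value.strip().lower()
    return _LANG_ALIASES.get(v, v)


def _matches_term(term: Term, c: Citation) -> bool:
    tag = term.tag
    if tag is FieldTag.TIAB:
        return match_phrase(c, term.text, "TIAB")
    if tag is FieldTag.TW:
        return match_phrase(c, term.text, "TIAB") or match_mesh(c, term.text)
    if tag is FieldTag.MH_NOEXP:
        return match_mesh(c, term.text)
    if tag is FieldTag.LA:
        return _lang_canon(c.language) == _lang_canon(term.text)
    if tag is FieldTag.DP:
        if not re.fullmatch(r"\d{4}", term.text):
            raise ValueError(f"[dp] supports 4-digit years only, got {term.text!r}")
        return c.pub_year == int(term.text)
    if tag is FieldTag.SB:
        if term.text.strip().lower() != "medline":
            raise UnsupportedSubsetError(f"unsupported subset {term.text!r}[sb]")
        return c.status is Status.MEDLINE
    if tag is FieldTag.HASABSTRACT:
        return c.has_abstract
    raise TypeError(f"unhandled tag {tag}")


def evaluate(q: Query, corpus: Corpus) -> set[str]:
    """Evaluate a query over a corpus, returning the set of matching PMIDs."""
    if isinstance(q, Term):
        return {c.pmid for c in corpus if _matches_term(q, c)}
    if isinstance(q, And):
        sets = [evaluate(child, corpus) for child in q.children]
        return set.intersection(*sets)
    if isinstance(q, Or):
        sets = [evaluate(child, corpus) for child in q.children]
        return set.union(*sets)
    if isinstance(q, Not):
        return evaluate(q.left, corpus) - evaluate(q.right, corpus)
    raise TypeError(f"cannot evaluate node {q!r} (OvidSP queries must be translated first)")
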