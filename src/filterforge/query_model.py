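"""Boolean query AST with OvidSP and PubMed parsers, translation and rendering.

The AST is shared by both syntaxes: internal nodes are ``AND``/``OR``
(n-ary, flattened) and binary ``NOT`` (relative complement, ``left NOT
right``).  Leaves are either :class:`Term` (a phrase plus a PubMed field
tag) or :class:`OvidTerm` (a phrase plus an OvidSP delimiter, ``.mp.`` or
``/``).

Operator precedence for unparenthesized input is NOT > AND > OR.  PubMed's
own left-to-right evaluation is deliberately not emulated: every query
string this package renders is fully parenthesized wherever structure
nests, so rendering is deterministic and safe to paste into PubMed.

Term text keeps its source case; matching downstream is case-insensitive.
Translation between syntaxes is purely structural: ``.mp.`` becomes
``[tw]`` and ``/`` becomes ``[mh:noexp]``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "FieldTag", "TERM_TAGS", "LIMIT_TAGS",
    "Query", "Term", "OvidTerm", "OvidDelimiter", "And", "Or", "Not",
    "QueryParseError",
    "parse_ovid", "parse_pubmed", "render_pubmed", "render_ovid",
    "translate_ovid_to_pubmed", "retag", "invert_heading",
]


class FieldTag(enum.Enum):
    """PubMed field tags understood by the retrieval engine.

    ``TW`` searches title, abstract and MeSH descriptor fields; ``TIAB``
    title/abstract only; ``MH_NOEXP`` the MeSH field alone, without tree
    explosion.  The remaining tags are limits (language, date, subset,
    has-abstract).
    """

    TW = "tw"
    TIAB = "tiab"
    MH_NOEXP = "mh:noexp"
    LA = "la"
    DP = "dp"
    SB = "sb"
    HASABSTRACT = "hasabstract"


TERM_TAGS = frozenset({FieldTag.TW, FieldTag.TIAB, FieldTag.MH_NOEXP})
LIMIT_TAGS = frozenset(FieldTag) - TERM_TAGS


class OvidDelimiter(enum.Enum):
    MP = ".mp."      # multi-purpose: title/abstract/subject-heading textword
    SLASH = "/"      # subject heading (MeSH), unexploded


class Query:
    """Base class for AST nodes."""

    def leaves(self) -> Iterator["Term | OvidTerm"]:
        if isinstance(self, (Term, OvidTerm)):
            yield self  # type: ignore[misc]
        elif isinstance(self, (And, Or)):
            for child in self.children:
                yield from child.leaves()
        elif isinstance(self, Not):
            yield from self.left.leaves()
            yield from self.right.leaves()


@dataclass(frozen=True)
class Term(Query):
    text: str
    tag: FieldTag

    def __post_init__(self) -> None:
        if self.tag is not FieldTag.HASABSTRACT:
            if not self.text or self.text != self.text.strip():
                raise ValueError(f"term text {self.text!r} empty or not stripped")


@dataclass(frozen=True)
class OvidTerm(Query):
    text: str
    delimiter: OvidDelimiter

    def __post_init__(self) -> None:
        if not self.text or self.text != self.text.strip():
            raise ValueError(f"term text {self.text!r} empty or not stripped")


@dataclass(frozen=True)
class And(Query):
    children: tuple[Query, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires at least 2 children")


@dataclass(frozen=True)
class Or(Query):
    children: tuple[Query, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires at least 2 children")


@dataclass(frozen=True)
class Not(Query):
    left: Query
    right: Query


class QueryParseError(ValueError):
    def __init__(self, message: str, offset: int | None = None) -> None:
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)
        self.offset = offset


# ---------------------------------------------------------------------------
# Tokenization shared by both parsers: operators and parentheses split the
# input; everything between them is term text handled per syntax.

_STRUCT_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|\bNOT\b", re.IGNORECASE)


def _lex(text: str) -> list[tuple[str, str, int]]:
    """Split into (kind, value, offset) tokens; kind in {op, paren, text}."""
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    for m in _STRUCT_RE.finditer(text):
        chunk = text[pos:m.start()]
        if chunk.strip():
            tokens.append(("text", chunk.strip(), pos + len(chunk) - len(chunk.lstrip())))
        tok = m.group(0)
        if tok in "()":
            tokens.append(("paren", tok, m.start()))
        else:
            tokens.append(("op", tok.upper(), m.start()))
        pos = m.end()
    tail = text[pos:]
    if tail.strip():
        tokens.append(("text", tail.strip(), pos + len(tail) - len(tail.lstrip())))
    return tokens


class _Parser:
    """Recursive-descent parser over lexed tokens; leaf handling is injected."""

    def __init__(self, tokens: list[tuple[str, str, int]], leaf) -> None:
        self.tokens = tokens
        self.pos = 0
        self.leaf = leaf

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def parse(self) -> Query:
        node = self.or_expr()
        if self.peek() is not None:
            kind, value, offset = self.peek()
            raise QueryParseError(f"unexpected {value!r}", offset)
        return node

    def or_expr(self) -> Query:
        children = [self.and_expr()]
        while self.peek() and self.peek()[:2] == ("op", "OR"):
            self.pos += 1
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> Query:
        children = [self.not_expr()]
        while self.peek() and self.peek()[:2] == ("op", "AND"):
            self.pos += 1
            children.append(self.not_expr())
        return children[0] if len(children) == 1 else And(tuple(children))

    def not_expr(self) -> Query:
        node = self.primary()
        while self.peek() and self.peek()[:2] == ("op", "NOT"):
            self.pos += 1
            node = Not(node, self.primary())
        return node

    def primary(self) -> Query:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query")
        kind, value, offset = tok
        if kind == "paren" and value == "(":
            self.pos += 1
            node = self.or_expr()
            closing = self.peek()
            if not closing or closing[:2] != ("paren", ")"):
                raise QueryParseError("unbalanced parenthesis", offset)
            self.pos += 1
            return node
        if kind == "text":
            self.pos += 1
            return self.leaf(value, offset)
        raise QueryParseError(f"unexpected {value!r}", offset)


# ---------------------------------------------------------------------------
# OvidSP syntax


def _ovid_leaf(text: str, offset: int) -> OvidTerm:
    if text.lower().endswith(".mp."):
        return OvidTerm(text[:-4].strip(), OvidDelimiter.MP)
    if text.endswith("/"):
        return OvidTerm(text[:-1].strip(), OvidDelimiter.SLASH)
    raise QueryParseError(
        f"term {text!r} lacks a recognized OvidSP delimiter (.mp. or /)", offset
    )


def parse_ovid(text: str) -> Query:
    """Parse an OvidSP filter string into an AST of :class:`OvidTerm` leaves."""
    return _Parser(_lex(text), _ovid_leaf).parse()


def render_ovid(q: Query) -> str:
    """Render an AST with OvidTerm leaves back to OvidSP syntax."""
    return _render(q, _ovid_term_str)


def _ovid_term_str(leaf: Query) -> str:
    if not isinstance(leaf, OvidTerm):
        raise TypeError(f"expected OvidTerm leaf, got {leaf!r}")
    if leaf.delimiter is OvidDelimiter.MP:
        return f"{leaf.text}.mp."
    return f"{leaf.text}/"


# ---------------------------------------------------------------------------
# PubMed syntax

_TAG_BY_VALUE = {t.value: t for t in FieldTag}
_PUBMED_TERM_RE = re.compile(r"^(.*?)\[([A-Za-z:]+)\]$")
# Straight and typographic double quotes are both accepted around hasabstract.
_HASABSTRACT_RE = re.compile(r'^["“”]hasabstract["“”]$', re.IGNORECASE)


def _pubmed_leaf(text: str, offset: int) -> Term:
    if _HASABSTRACT_RE.match(text):
        return Term("", FieldTag.HASABSTRACT)
    m = _PUBMED_TERM_RE.match(text)
    if not m:
        raise QueryParseError(f"term {text!r} lacks a [tag] suffix", offset)
    tag = _TAG_BY_VALUE.get(m.group(2).lower())
    if tag is None or tag is FieldTag.HASABSTRACT:
        raise QueryParseError(f"unknown field tag [{m.group(2)}]", offset)
    return Term(m.group(1).strip(), tag)


def parse_pubmed(text: str) -> Query:
    """Parse a PubMed query string (``[tag]`` suffixes, quoted hasabstract)."""
    return _Parser(_lex(text), _pubmed_leaf).parse()


def _pubmed_term_str(leaf: Query) -> str:
    if not isinstance(leaf, Term):
        raise TypeError(f"expected Term leaf, got {leaf!r}")
    if leaf.tag is FieldTag.HASABSTRACT:
        return '"hasabstract"'
    return f"{leaf.text}[{leaf.tag.value}]"


def _render(q: Query, term_str) -> str:
    def wrap(child: Query) -> str:
        inner = rec(child)
        return f"({inner})" if isinstance(child, (And, Or, Not)) else inner

    def rec(node: Query) -> str:
        if isinstance(node, (Term, OvidTerm)):
            return term_str(node)
        if isinstance(node, Or):
            return " OR ".join(wrap(c) for c in node.children)
        if isinstance(node, And):
            return " AND ".join(wrap(c) for c in node.children)
        if isinstance(node, Not):
            return f"{wrap(node.left)} NOT {wrap(node.right)}"
        raise TypeError(f"not a query node: {node!r}")

    return rec(q)


def render_pubmed(q: Query) -> str:
    """Deterministic rendering: single spaces around operators, parentheses
    exactly where the AST nests, tags lowercase in brackets."""
    return _render(q, _pubmed_term_str)


# ---------------------------------------------------------------------------
# Translation and retagging


def _map_leaves(q: Query, fn) -> Query:
    if isinstance(q, (Term, OvidTerm)):
        return fn(q)
    if isinstance(q, And):
        return And(tuple(_map_leaves(c, fn) for c in q.children))
    if isinstance(q, Or):
        return Or(tuple(_map_leaves(c, fn) for c in q.children))
    if isinstance(q, Not):
        return Not(_map_leaves(q.left, fn), _map_leaves(q.right, fn))
    raise TypeError(f"not a query node: {q!r}")


def translate_ovid_to_pubmed(q: Query) -> Query:
    """Convert OvidSP delimiters to PubMed tags: ``.mp.`` -> ``[tw]``,
    ``/`` -> ``[mh:noexp]``.  Boolean structure and term text are unchanged."""

    def fn(leaf: Query) -> Term:
        if not isinstance(leaf, OvidTerm):
            raise ValueError(f"expected OvidTerm leaves, got {leaf!r}")
        tag = FieldTag.TW if leaf.delimiter is OvidDelimiter.MP else FieldTag.MH_NOEXP
        return Term(leaf.text, tag)

    return _map_leaves(q, fn)


def invert_heading(text: str) -> str:
    """Rewrite a MeSH inverted form ``"X, Y"`` (single comma) to natural word
    order ``"Y X"``; text without exactly one comma is returned unchanged."""
    if text.count(",") == 1:
        head, tail = (part.strip() for part in text.split(","))
        if head and tail:
            return f"{tail} {head}"
    return text


def retag(q: Query, new_tag: FieldTag) -> Query:
    """Replace every term tag with *new_tag*.

    MeSH-tagged leaves in inverted form are first rewritten to natural word
    order (``Ventricular dysfunction, Left`` -> ``Left Ventricular
    dysfunction``), since an inverted heading only makes sense against the
    MeSH field.  Raises on queries containing limit tags: limits are applied
    separately from filter terms.
    """
    if new_tag not in TERM_TAGS:
        raise ValueError(f"cannot retag to limit tag {new_tag}")

    def fn(leaf: Query) -> Term:
        if not isinstance(leaf, Term):
            raise ValueError(f"retag expects PubMed Term leaves, got {leaf!r}")
        if leaf.tag not in TERM_TAGS:
            raise ValueError(f"retag applies to term tags only, found [{leaf.tag.value}]")
        text = invert_heading(leaf.text) if leaf.tag is FieldTag.MH_NOEXP else leaf.text
        return Term(text, new_tag)

    return _map_leaves(q, fn)
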