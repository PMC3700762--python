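"""Citation data model and reader/writer for the MEDLINE tagged format.

The dialect handled here is the one PubMed exports (``.nbib`` / EFetch
``rettype=medline``): four-character field tags padded with spaces, a
``- `` separator, and continuation lines indented six spaces.  Only the
fields the downstream pipeline consumes are modeled (PMID, TI, AB, MH,
LA, DP, STAT); everything else is ignored on read and omitted on write.

MeSH headings are reduced to bare descriptors on load: the major-topic
star is stripped and any ``/subheading`` qualifier truncated, because
retrieval and subset analysis match descriptors only.
"""

from __future__ import annotations

import enum
import logging
import re
import textwrap
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = ["Status", "Citation", "Corpus", "read_medline", "write_medline"]


class Status(enum.Enum):
    """NLM processing status of a citation.

    ``PUBLISHER`` and ``IN_PROCESS`` records have not yet been indexed and
    therefore carry no MeSH headings; ``MEDLINE`` records are fully indexed;
    ``PUBMED_NOT_MEDLINE`` records are permanently outside Medline's scope.
    """

    MEDLINE = "MEDLINE"
    IN_PROCESS = "In-Process"
    PUBLISHER = "Publisher"
    PUBMED_NOT_MEDLINE = "PubMed-not-MEDLINE"


_STAT_VALUES = {s.value.lower(): s for s in Status}
# A couple of historical spellings seen in exports.
_STAT_VALUES["in-data-review"] = Status.IN_PROCESS
_STAT_VALUES["medline"] = Status.MEDLINE

_UNINDEXED = (Status.PUBLISHER, Status.IN_PROCESS)


def _clean_heading(raw: str) -> str:
    """Strip the major-topic marker and truncate at the first qualifier."""
    h = raw.strip().lstrip("*")
    return h.split("/", 1)[0].strip()


@dataclass(frozen=True)
class Citation:
    """One MEDLINE record, reduced to the fields the pipeline reads."""

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_headings: tuple[str, ...] = ()
    language: str = "eng"
    pub_year: int = 2010
    status: Status = Status.MEDLINE

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("citation requires a nonempty PMID")
        if not 1800 <= self.pub_year <= 2100:
            raise ValueError(f"PMID {self.pmid}: pub_year {self.pub_year} outside [1800, 2100]")
        for h in self.mesh_headings:
            if "/" in h or h.startswith("*"):
                raise ValueError(f"PMID {self.pmid}: heading {h!r} not reduced to a bare descriptor")
        if self.status in _UNINDEXED and self.mesh_headings:
            raise ValueError(
                f"PMID {self.pmid}: status {self.status.value} implies no MeSH headings"
            )

    @property
    def has_abstract(self) -> bool:
        """True iff the abstract is nonempty after whitespace normalization."""
        return bool(self.abstract.strip())


def _pmid_key(pmid: str) -> tuple[int, str]:
    # Numeric PMIDs sort numerically; anything else falls back to text order.
    return (int(pmid), "") if pmid.isdigit() else (-1, pmid)


class Corpus:
    """A set of citations keyed by PMID, iterated in ascending-PMID order."""

    def __init__(self, citations: Iterable[Citation] = ()) -> None:
        self._by_pmid: dict[str, Citation] = {}
        for c in citations:
            self.add(c)

    def add(self, citation: Citation) -> None:
        if citation.pmid in self._by_pmid:
            raise ValueError(f"duplicate PMID {citation.pmid}")
        self._by_pmid[citation.pmid] = citation

    def __len__(self) -> int:
        return len(self._by_pmid)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self._by_pmid

    def __getitem__(self, pmid: str) -> Citation:
        return self._by_pmid[pmid]

    def __iter__(self) -> Iterator[Citation]:
        for pmid in sorted(self._by_pmid, key=_pmid_key):
            yield self._by_pmid[pmid]

    def pmids(self) -> list[str]:
        return sorted(self._by_pmid, key=_pmid_key)

    def subset(self, pmids: Iterable[str]) -> list[Citation]:
        """Citations for the given PMIDs, in ascending-PMID order."""
        return [self._by_pmid[p] for p in sorted(set(pmids), key=_pmid_key)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._by_pmid == other._by_pmid

    def __repr__(self) -> str:
        return f"Corpus({len(self)} citations)"


_TAG_RE = re.compile(r"^([A-Z]{2,4})\s*- (.*)$")
_YEAR_RE = re.compile(r"\b(1[89]\d{2}|20\d{2}|2100)\b")


def _records(stream: Iterable[str]) -> Iterator[list[tuple[str, str]]]:
    """Group a tagged stream into records of (tag, joined value) pairs."""
    fields: list[tuple[str, str]] = []
    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            if fields:
                yield fields
                fields = []
            continue
        if line.startswith("      ") and fields:
            tag, value = fields[-1]
            fields[-1] = (tag, value + " " + line.strip())
            continue
        m = _TAG_RE.match(line)
        if m:
            fields.append((m.group(1), m.group(2).strip()))
        # Unrecognized non-continuation lines are ignored.
    if fields:
        yield fields


def read_medline(stream: IO[str] | Iterable[str]) -> Corpus:
    """Parse a MEDLINE tagged stream into a :class:`Corpus`.

    Multi-line TI/AB values are joined with single spaces; MH values are
    reduced to bare descriptors; DP is reduced to its first 4-digit year.
    Unknown tags are ignored.  Raises ``ValueError`` on a record without a
    PMID, a duplicate PMID, or a DP field without a parseable year.
    """
    corpus = Corpus()
    for index, fields in enumerate(_records(stream), start=1):
        data: dict[str, str] = {}
        headings: list[str] = []
        for tag, value in fields:
            if tag == "MH":
                h = _clean_heading(value)
                if h:
                    headings.append(h)
            elif tag in ("TI", "AB", "DP", "STAT"):
                data.setdefault(tag, value)
            elif tag == "LA":
                data.setdefault("LA", value)
            elif tag == "PMID":
                data.setdefault("PMID", value)
        pmid = data.get("PMID", "")
        if not pmid:
            raise ValueError(f"record {index} has no PMID field")
        dp = data.get("DP", "")
        year_match = _YEAR_RE.search(dp)
        if dp and not year_match:
            raise ValueError(f"PMID {pmid}: DP field {dp!r} has no 4-digit year")
        stat_raw = data.get("STAT", "MEDLINE")
        status = _STAT_VALUES.get(stat_raw.lower())
        if status is None:
            logger.warning(
                "PMID %s: unrecognized STAT value %r, treating as Publisher (unindexed)",
                pmid, stat_raw,
            )
            status = Status.PUBLISHER
        if status in _UNINDEXED and headings:
            logger.warning(
                "PMID %s: %s record carries MH fields; dropping headings", pmid, status.value
            )
            headings = []
        if pmid in corpus:
            raise ValueError(f"duplicate PMID {pmid}")
        corpus.add(
            Citation(
                pmid=pmid,
                title=data.get("TI", ""),
                abstract=data.get("AB", ""),
                mesh_headings=tuple(headings),
                language=data.get("LA", "eng"),
                pub_year=int(year_match.group(0)) if year_match else 2010,
                status=status,
            )
        )
    return corpus


def _emit(out: IO[str], tag: str, value: str) -> None:
    lead = f"{tag:<4}- "
    wrapped = textwrap.wrap(
        value, width=80, initial_indent=lead, subsequent_indent="      ",
        break_long_words=False, break_on_hyphens=False,
    ) or [lead.rstrip() + " "]
    for line in wrapped:
        out.write(line + "\n")


def write_medline(corpus: Corpus, stream: IO[str]) -> None:
    """Write *corpus* in the tagged dialect accepted by :func:`read_medline`.

    Records are emitted in ascending-PMID order; long values wrap at 80
    characters with six-space continuation indents, so output round-trips
    field-for-field through :func:`read_medline`.
    """
    first = True
    for c in corpus:
        if not first:
            stream.write("\n")
        first = False
        _emit(stream, "PMID", c.pmid)
        _emit(stream, "STAT", c.status.value)
        _emit(stream, "DP", str(c.pub_year))
        if c.title:
            _emit(stream, "TI", c.title)
        if c.abstract:
            _emit(stream, "AB", c.abstract)
        _emit(stream, "LA", c.language)
        for h in c.mesh_headings:
            _emit(stream, "MH", h)
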