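"""End-to-end orchestration of the five pipeline phases plus assembly.

``run_pipeline`` takes one configuration -- a corpus (file or synthetic
spec), a filter in PubMed syntax, study limits and discovery thresholds --
and produces a :class:`RunReport` holding the retrieval counts, per-subset
shares, the candidate table, the greedy selection trace and the assembled
two-branch filter string.

Reported shares follow the reporting conventions used throughout:
percentages are rounded half-up to one decimal place (5.18% prints as
5.2%), except the headline lost fraction, which is rounded to a whole
number once it reaches 10%.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any

from filterforge._version import __version__ as _version
from filterforge.filter_assembly import assemble
from filterforge.greedy_selection import SelectionResult, greedy_select
from filterforge.lost_set_pipeline import LostSet, StudyLimits, compute_lost_set
from filterforge.medline_corpus import Corpus, read_medline
from filterforge.query_model import Query, parse_pubmed, render_pubmed
from filterforge.synthetic_corpus import CorpusSpec, generate
from filterforge.term_discovery import DEFAULT_STOPLIST, CandidateTerm, discover_candidates

logger = logging.getLogger(__name__)

__all__ = ["percent", "headline_percent", "PipelineConfig", "RunReport", "run_pipeline"]


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Share of *count* in *total* as a percentage, rounded half-up.

    Half-up (not banker's) rounding reproduces conventional reporting:
    23/444 -> 5.2, 157/834 -> 18.8, 346/834 -> 41.5.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(count) * 100 / Decimal(total)).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(value)


def headline_percent(count: int, total: int) -> float:
    """Headline share: whole number once >= 10%, else one decimal."""
    one_dp = percent(count, total, decimals=1)
    if one_dp >= 10.0:
        return float(percent(count, total, decimals=0))
    return one_dp


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs of one pipeline run.

    Exactly one of ``corpus_path`` and ``corpus_spec`` must be given.
    ``filter_query`` is the validated filter in PubMed syntax with
    ``[tw]``/``[mh:noexp]`` tags.
    """

    filter_query: str
    corpus_path: str | Path | None = None
    corpus_spec: CorpusSpec | None = None
    limits: StudyLimits = StudyLimits()
    min_frequency: int = 10
    recall_cutoff: float = 0.05
    max_phrase_len: int = 5
    stoplist: frozenset[str] = DEFAULT_STOPLIST
    blocklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.corpus_path is None) == (self.corpus_spec is None):
            raise ValueError("provide exactly one of corpus_path and corpus_spec")


@dataclass(frozen=True)
class RunReport:
    """Machine-readable result of one pipeline run."""

    n_mesh_retrieved: int
    n_tiab_retrieved: int
    n_overlap: int
    n_lost: int
    lost_fraction_pct: float
    subsets: dict[str, dict[str, float]]          # term -> {size, share_pct}
    candidates: list[CandidateTerm]
    selection: SelectionResult | None
    validated_query: str
    combined_filter: str
    config: dict[str, Any]
    seed: int | None
    version: str = _version

    def selection_trace(self) -> list[dict[str, Any]]:
        """Per-step rows: term, marginal gain, cumulative count, cumulative %."""
        if self.selection is None:
            return []
        rows = []
        cum = 0
        for term, gain, rec in zip(
            self.selection.selected,
            self.selection.marginal_gains,
            self.selection.cumulative_recall,
        ):
            cum += gain
            rows.append({
                "term": term,
                "marginal_gain": gain,
                "cumulative_n": cum,
                "cumulative_pct": percent(cum, self.n_lost),
            })
        return rows

    def to_text(self) -> str:
        lines = [
            f"filterforge {self.version} pipeline report",
            f"#1 (MeSH-empowered): {self.n_mesh_retrieved}",
            f"#2 (textword-restricted): {self.n_tiab_retrieved} "
            f"(overlap with #1: {self.n_overlap})",
            f"#3 (Lost Set = #1 NOT #2): {self.n_lost} ({self.lost_fraction_pct}% of #1)",
            "",
            "Per-term subsets of the Lost Set:",
        ]
        for term, row in self.subsets.items():
            lines.append(f"  {term}: {row['size']:.0f} ({row['share_pct']}% of lost)")
        lines.append("")
        lines.append("Candidate terms (phrase, subset, raw freq, record occurrence, subset %):")
        if not self.candidates:
            lines.append("  (none)")
        for cand in self.candidates:
            size = int(self.subsets.get(cand.source_subset, {}).get("size", 0))
            share = percent(cand.record_occurrence, size) if size else 0.0
            lines.append(
                f"  {cand.phrase}\t{cand.source_subset}\t{cand.raw_frequency}\t"
                f"{cand.record_occurrence}\t{share}%"
            )
        lines.append("")
        lines.append("Greedy selection trace:")
        trace = self.selection_trace()
        if not trace:
            lines.append("  (no terms selected)")
        for row in trace:
            lines.append(
                f"  {row['term']}\t+{row['marginal_gain']}\t"
                f"{row['cumulative_n']}/{self.n_lost}\t{row['cumulative_pct']}%"
            )
        lines.append("")
        lines.append("Assembled filter:")
        lines.append(f"  {self.combined_filter}")
        return "\n".join(lines)

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "counts": {
                "mesh_retrieved": self.n_mesh_retrieved,
                "tiab_retrieved": self.n_tiab_retrieved,
                "overlap": self.n_overlap,
                "lost": self.n_lost,
                "lost_fraction_pct": self.lost_fraction_pct,
            },
            "subsets": self.subsets,
            "candidates": [dataclasses.asdict(c) for c in self.candidates],
            "selection": self.selection_trace(),
            "rejected_redundant": (
                list(self.selection.rejected_redundant) if self.selection else []
            ),
            "validated_query": self.validated_query,
            "combined_filter": self.combined_filter,
        }


def _load_corpus(config: PipelineConfig) -> tuple[Corpus, int | None]:
    if config.corpus_spec is not None:
        return generate(config.corpus_spec), config.corpus_spec.seed
    path = Path(config.corpus_path)  # type: ignore[arg-type]
    with open(path, encoding="utf-8") as fh:
        return read_medline(fh), None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute phases 1-5 and assembly; any stage error aborts with its name."""
    stage = "corpus"
    try:
        corpus, seed = _load_corpus(config)

        stage = "parse-filter"
        filter_q: Query = parse_pubmed(config.filter_query)

        stage = "lost-set"
        lost_set: LostSet = compute_lost_set(filter_q, corpus, config.limits)
        logger.info(
            "lost set: |#1|=%d |#2|=%d |lost|=%d",
            len(lost_set.mesh_retrieved), len(lost_set.tiab_retrieved), len(lost_set.lost),
        )

        stage = "discovery"
        candidates: list[CandidateTerm] = []
        for term_text, members in lost_set.subsets.items():
            subset = corpus.subset(members)
            candidates.extend(
                discover_candidates(
                    subset,
                    source_subset=term_text,
                    min_frequency=config.min_frequency,
                    recall_cutoff=config.recall_cutoff,
                    max_len=config.max_phrase_len,
                    stoplist=config.stoplist,
                    blocklist=config.blocklist,
                )
            )

        stage = "selection"
        selection: SelectionResult | None = None
        if candidates and lost_set.lost:
            selection = greedy_select(candidates, lost_set.lost, corpus)

        stage = "assembly"
        extended = assemble(filter_q, selection if selection else ())

        n1, n2 = len(lost_set.mesh_retrieved), len(lost_set.tiab_retrieved)
        n_lost = len(lost_set.lost)
        subsets = {
            term: {
                "size": float(len(members)),
                "share_pct": percent(len(members), n_lost) if n_lost else 0.0,
            }
            for term, members in lost_set.subsets.items()
        }
        return RunReport(
            n_mesh_retrieved=n1,
            n_tiab_retrieved=n2,
            n_overlap=len(lost_set.overlap),
            n_lost=n_lost,
            lost_fraction_pct=headline_percent(n_lost, n1) if n1 else 0.0,
            subsets=subsets,
            candidates=candidates,
            selection=selection,
            validated_query=render_pubmed(filter_q),
            combined_filter=extended.render(),
            config={
                "filter": config.filter_query,
                "limits": dataclasses.asdict(config.limits) | {"subset": config.limits.subset.value},
                "min_frequency": config.min_frequency,
                "recall_cutoff": config.recall_cutoff,
                "stoplist_size": len(config.stoplist),
                "blocklist": sorted(config.blocklist),
            },
            seed=seed,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
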