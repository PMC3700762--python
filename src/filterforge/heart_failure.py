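"""The validated heart-failure filter: the package's worked example.

This module carries the four-term heart failure search filter (OvidSP
Medline form and its PubMed translation), the study search strings run
against the April-2011 database, the retrieval counts reported for that
run, and a synthetic-corpus specification that reproduces the same
statistical regime at desk scale.  All of it is *input data* for the
pipeline and the acceptance checks -- nothing here is computed.
"""

from __future__ import annotations

from filterforge.lost_set_pipeline import StudyLimits, SubsetLimit
from filterforge.synthetic_corpus import ConceptSpec, CorpusSpec

__all__ = [
    "OVID_FILTER", "PUBMED_TRANSLATION", "FILTER_TERMS_TW",
    "MESH_SEARCH", "TIAB_SEARCH", "VALIDATED_FILTER", "SELECTED_TERMS",
    "FULL_FILTER", "STUDY_LIMITS", "PUBLISHED_COUNTS", "DEFAULT_BLOCKLIST",
    "heart_failure_regime",
]

#: The validated OvidSP Medline heart failure filter.
OVID_FILTER = (
    "Heart failure.mp. OR Ventricular dysfunction, Left/ OR cardiomyopathy.mp. "
    "OR left ventricular ejection fraction.mp."
)

#: Its PubMed translation (.mp. -> [tw], / -> [mh:noexp]).
PUBMED_TRANSLATION = (
    "Heart failure[tw] OR Ventricular dysfunction, Left[mh:noexp] OR "
    "cardiomyopathy[tw] OR left ventricular ejection fraction[tw]"
)

#: The translation as run in search #1, with the inverted MeSH term changed
#: to natural word order (PubMed maps the textword back to the inverted
#: heading, so MeSH-based retrieval is unaffected).
FILTER_TERMS_TW = (
    "heart failure[tw] OR left ventricular dysfunction[mh:noexp] OR "
    "cardiomyopathy[tw] OR left ventricular ejection fraction[tw]"
)

#: Search #1: MeSH-empowered retrieval under the study limits.
MESH_SEARCH = (
    "(heart failure[tw] OR left ventricular dysfunction[mh:noexp] OR "
    "cardiomyopathy[tw] OR left ventricular ejection fraction[tw]) AND "
    'English[la] AND 2010[dp] AND "hasabstract" AND Medline[sb]'
)

#: Search #2: the same terms restricted to title/abstract fields.
TIAB_SEARCH = (
    "(heart failure[tiab] OR left ventricular dysfunction[tiab] OR "
    "cardiomyopathy[tiab] OR left ventricular ejection fraction[tiab]) AND "
    'English[la] AND 2010[dp] AND "hasabstract" AND Medline[sb]'
)

#: The validated translation as it appears inside the published full filter.
VALIDATED_FILTER = (
    "heart failure[tw] OR ventricular dysfunction, left[mh:noexp] OR "
    "cardiomyopathy[tw] OR left ventricular ejection fraction[tw]"
)

#: Supplementary terms in published order (greedy selection order).
SELECTED_TERMS = (
    "cardiac resynchronization",
    "cardiac failure",
    "left ventricular systolic dysfunction",
    "LV dysfunction",
    "left ventricular diastolic dysfunction",
)

#: The full two-branch PubMed heart failure filter.
FULL_FILTER = (
    "((heart failure[tw] OR ventricular dysfunction, left[mh:noexp] OR "
    "cardiomyopathy[tw] OR left ventricular ejection fraction[tw]) AND "
    "Medline[sb]) OR ((heart failure[tiab] OR left ventricular "
    "dysfunction[tiab] OR cardiomyopathy[tiab] OR left ventricular ejection "
    "fraction[tiab] OR cardiac resynchronization[tiab] OR cardiac "
    "failure[tiab] OR left ventricular systolic dysfunction[tiab] OR LV "
    "dysfunction[tiab] OR left ventricular diastolic dysfunction[tiab]) NOT "
    "Medline[sb])"
)

#: Limits used by searches #1 and #2.
STUDY_LIMITS = StudyLimits(
    language="English", pub_year=2010, require_abstract=True,
    subset=SubsetLimit.MEDLINE_ONLY,
)

#: Retrieval counts reported for the filter's April-2011 run against the
#: live database.  Keys: the three searches, per-term subset sizes, each
#: candidate's record occurrence in (own subset, full lost set), the best
#: single term's lost-set count, and the final combination's coverage.
PUBLISHED_COUNTS: dict = {
    "mesh_retrieved": 6829,
    "tiab_retrieved": 5995,
    "lost": 834,
    "subsets": {
        "heart failure": 346,
        "left ventricular dysfunction": 444,
        "cardiomyopathy": 76,
    },
    "candidates": {
        # phrase: (subset, occurrence in subset, occurrence in full lost set)
        "cardiac failure": ("heart failure", 33, 38),
        "cardiac resynchronization": ("heart failure", 30, 41),
        "LV dysfunction": ("left ventricular dysfunction", 29, 30),
        "left ventricular systolic dysfunction": ("left ventricular dysfunction", 29, 30),
        "left ventricular diastolic dysfunction": ("left ventricular dysfunction", 23, 23),
        "Chagas disease": ("cardiomyopathy", 14, None),
    },
    "best_single_term_lost_occurrence": 41,
    "combined_lost_coverage": 157,
}

#: Phrases excluded from candidacy by explicit curation: "left ventricular"
#: is an incomplete concept, and Chagas disease is related to but not
#: equivalent with cardiomyopathy.
DEFAULT_BLOCKLIST: frozenset[str] = frozenset({"left ventricular", "chagas disease"})


def heart_failure_regime(seed: int, n_records: int = 3000) -> CorpusSpec:
    """Synthetic corpus in the heart-failure study's statistical regime.

    The canonical-phrase probability of 0.88 plants a 12% lost fraction in
    every concept, and the alternatives carry their reported conditional
    subset frequencies (9.5%/8.7% for the heart-failure subset,
    6.5%/6.5%/5.2% for left ventricular dysfunction, 18.4% for Chagas
    disease in the cardiomyopathy subset).  Concept weights concentrate the
    lost set on the heart-failure concept so that, at 3,000 records, its
    two alternatives have expected occurrences well clear of the discovery
    thresholds, while the lower-weight concepts exercise the
    below-threshold regime; see ``planted_truth`` for the resulting
    classifications.
    """
    concepts = (
        ConceptSpec(
            mesh_heading="Heart Failure",
            canonical_phrase="heart failure",
            weight=0.95,
            p_mesh=1.0,
            p_phrase_given_mesh=0.88,
            alternatives=(
                ("cardiac failure", 0.095),
                ("cardiac resynchronization", 0.087),
            ),
        ),
        ConceptSpec(
            mesh_heading="Ventricular Dysfunction, Left",
            canonical_phrase="left ventricular dysfunction",
            weight=0.04,
            p_mesh=1.0,
            p_phrase_given_mesh=0.88,
            alternatives=(
                ("lv dysfunction", 0.065),
                ("left ventricular systolic dysfunction", 0.065),
                ("left ventricular diastolic dysfunction", 0.052),
            ),
        ),
        ConceptSpec(
            mesh_heading="Cardiomyopathy",
            canonical_phrase="cardiomyopathy",
            weight=0.01,
            p_mesh=1.0,
            p_phrase_given_mesh=0.88,
            alternatives=(("chagas disease", 0.184),),
        ),
    )
    return CorpusSpec(n_records=n_records, fraction_indexed=0.9, concepts=concepts, seed=seed)
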