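# Methods

This note documents the models, conventions and numerical choices behind
filterforge, in the order the pipeline runs them.

## Retrieval model

Queries are boolean ASTs over field-tagged phrase terms. The engine
emulates the slice of PubMed semantics the method depends on, and no more:

* **Tokenization.** Text is lowercased and split on every non-alphanumeric
  character; empty fragments are dropped. No stemming, stopword removal or
  truncation happens at match time.
* **`[tiab]`** — a phrase matches iff its token sequence occurs as a
  contiguous run in the title or in the abstract. This is the adjacency
  condition of double-quoted phrase searching: `left ventricular
  dysfunction` does not match "dysfunction of the left ventricle". Phrases
  never match across the title/abstract boundary.
* **`[mh:noexp]`** — equality against an assigned MeSH descriptor after
  case folding and inverted-form normalization (below). The MeSH tree is
  never exploded, matching the `:noexp` qualifier's contract.
* **`[tw]`** — the union of the two. Real PubMed `[tw]` also scans
  substance names and a few other fields; the method only depends on
  title, abstract and MeSH descriptors, so `[tw]` is deliberately
  simplified to that union. A practical consequence used by tests: for the
  same text, `[tiab]` hits are always a subset of `[tw]` hits.
* **Limits.** `English[la]` (with English↔eng aliasing), `2010[dp]`
  (year-only equality; anything else is rejected), `"hasabstract"`
  (nonempty abstract), `Medline[sb]` (status = MEDLINE; any other subset
  is rejected as unsupported).
* **Operators.** `AND`/`OR` are n-ary set intersection/union; `NOT` is
  binary relative complement within the corpus, never global negation.
  Parsing precedence for unparenthesized input is NOT > AND > OR; the
  renderer parenthesizes every nested compound, so every string the
  package emits is unambiguous under any evaluation order, including
  PubMed's own left-to-right rule.

**Inverted-heading normalization.** A heading of the form `X, Y` with a
single comma (e.g. `Ventricular Dysfunction, Left`) is read in natural
word order (`left ventricular dysfunction`) before tokenization; headings
without a comma normalize to their own token sequence. This reproduces the
natural-word-order mapping between the inverted descriptor and its
textword form without requiring a MeSH vocabulary download. Headings with
multiple commas are left as written — a known simplification.

## Lost-set analysis

Search #1 applies the filter with `[tw]`/`[mh:noexp]` tags; search #2 is
the same filter retagged to `[tiab]`; both carry identical limits; the
Lost Set is `#1 NOT #2`. `|lost| + |#1 ∩ #2| = |#1|` always, and the
overlap is reported explicitly because `#2 ⊆ #1` is *not* guaranteed once
an `[mh:noexp]` term is present (a record can contain the phrase without
carrying the heading).

Each filter term with a MeSH interpretation (an `[mh:noexp]` term, or a
`[tw]` term whose text matches a normalized heading somewhere in the
corpus) defines a subset of the Lost Set: records carrying that heading
whose titles/abstracts lack the term's natural-order phrase. Subsets may
overlap and are never forced disjoint; a term with no MeSH equivalent
(e.g. *left ventricular ejection fraction*) gets no subset because the
`[tw]`→`[tiab]` conversion cannot affect its retrieval.

## Term discovery

Per subset: pooled title+abstract tokens are frequency-ranked; tokens on
the stoplist or with raw frequency ≤ 10 are removed; the phrase contexts
of surviving tokens — all contiguous n-grams of 2–5 tokens containing the
token — are kept when their raw frequency is ≥ 10; finally a phrase
survives only if it retrieves strictly more than 5% of its own subset's
records and is not blocklisted.

Parameter conventions, all configurable:

| parameter | default | note |
|---|---|---|
| single-token floor | remove ≤ 10 occurrences | boundary removes exactly 10 |
| phrase floor | retain ≥ 10 occurrences | boundary retains exactly 10 |
| subset-recall cutoff | > 0.05 (strict) | 5/100 is removed, 23/444 kept |
| max phrase length | 5 tokens | |
| stoplist | ~60 function/boilerplate words | includes "patients" |
| blocklist | empty (heart-failure default: "left ventricular", "chagas disease") | |

The floors' boundary asymmetry (tokens *removed at* ≤ 10, phrases
*retained at* ≥ 10) is kept exactly as specified by the procedure this
implements; one consequence is that a phrase occurring exactly 10 times
whose tokens occur nowhere else is unreachable, since its seed tokens are
dropped first. Raw occurrence counts feed the floors; distinct-record
counts feed the recall cutoff. The stoplist and blocklist stand in for a
human review step: the stoplist drops tokens with no topical specificity,
the blocklist records judgment calls against whole phrases (an incomplete
concept, a related-but-not-equivalent disease). Both are explicit inputs,
logged into the run report, and the CLI's `discover --review` mode prints
below-cutoff phrases for manual curation.

## Greedy selection

Candidate phrases are scored by the number of Lost-Set records they match
as `[tiab]` phrases. Selection is standard greedy maximum coverage: take
the highest-retrieving term (T1), then repeatedly the term adding the most
not-yet-covered records (T2, T3, …), stopping when the best marginal gain
is zero. This formalizes the manual "best two-term, best three-term…"
combination search and inherits the classical (1 − 1/e) approximation
guarantee, which the tests verify against exhaustive search on small
instances. Ties are broken by higher individual recall, then
lexicographically smaller phrase, making the output invariant to candidate
order; tie-breaks are logged. Terms never adding coverage are reported as
redundant — coverage of selected terms always equals coverage of selected
plus redundant.

## Filter assembly

The extended filter is `(validated AND Medline[sb]) OR ((retagged
originals OR selected terms) NOT Medline[sb])`. Retagged originals precede
selected terms, in original order; a selected term duplicating an original
(case-insensitive exact phrase) is dropped with a warning. The subset
restrictions are complementary, so the branches' result sets are disjoint
and the combined retrieval restricted to MEDLINE-status records equals the
validated branch alone — the validated filter's behavior on indexed
content is provably untouched.

## Synthetic corpora

The generator emulates the one mechanism the pipeline measures: indexers
assign a MeSH heading from the full text, so the heading and its
natural-language phrase co-occur only imperfectly. Each record belongs to
at most one concept (mutually exclusive assignment by concept weight).
For an indexed record about a concept, the heading is assigned with
probability `p_mesh`; given the heading, the canonical phrase appears with
probability `p_phrase_given_mesh`, and when it does not, each alternative
phrase appears independently at its own conditional rate — so
`1 − p_phrase_given_mesh` is the concept's planted lost fraction and each
alternative's rate is its planted subset recall. Records about a concept
that do not receive the heading receive no phrase either; non-indexed
records (Publisher/In-Process, never any heading) run the same conditional
scheme, emulating not-yet-indexed content retrievable only by textwords.

Everything else is background noise: titles of 5–15 and abstracts of
80–250 tokens drawn uniformly from a synthetic 400-token pool, 2% of
records without abstracts, languages and years from small weighted pools
(98% eng / 2% fre; 97% 2010 / 3% 2009) so the study limits do real
filtering. Phrases are embedded as intact token runs inserted at chunk
boundaries (one phrase can never split another), because the matching
contract is adjacency-based; paraphrase and morphology noise are *not*
modeled. Generation is fully deterministic given the spec's seed.

What passing tests therefore show: the pipeline's set algebra, counting,
thresholding and selection are correct, and its statistical behavior
matches the planted parameters at realistic sizes. What they cannot show:
robustness to real natural language — inflection, hyphenation variants,
phrase-internal modifiers — or to the PubMed fields the engine does not
model.

### The heart-failure regime and recoverability margins

`heart_failure.heart_failure_regime(seed)` fixes the study conditions used
by the acceptance checks: 3,000 records, 90% indexed,
`p_phrase_given_mesh = 0.88` (12% lost fraction) for all three concepts,
and the alternatives at their published conditional rates
(0.095/0.087, 0.065/0.065/0.052, 0.184). Concept weights are 0.95 / 0.04 /
0.01: at 3,000 records a corpus can host at most ~320 lost records in
total, so the weights concentrate the lost set on the heart-failure
concept (subset ≈ 280) where its two alternatives are statistically
decidable, while the small subsets exercise the clearly-undiscoverable
regime.

`planted_truth` classifies each planted alternative as *recoverable*,
*borderline* or *unrecoverable* by comparing its expected record
occurrence and expected recall against the frequency floor and the recall
cutoff with a one-sided 99% binomial margin (z = 2.326). The three-way
split is essential: a rate like 8.7% sits within sampling noise of the 5%
cutoff at any subset size reachable in a 3,000-record corpus, so no seed-
stable yes/no prediction exists for it; recovery tests require every
recoverable phrase to be discovered and no unrecoverable (or unplanted)
phrase to appear, while borderline phrases may go either way.

## Reporting conventions

Percentages are rounded half-up to one decimal (5.18 → 5.2, 18.42 → 18.4);
the headline lost fraction is rounded to a whole number once it reaches
10%. All shares in a run report recompute exactly from the reported
counts.

## Problem sizes

The test suite runs 1,000 random query/corpus equivalence cases against a
truth-table oracle, 10,000 phrase-match cases against a string-containment
oracle, 25 greedy instances against a reference reimplementation and
exhaustive search (≤ 12 candidates, ≤ 60 records), and 20 regime corpora
of 3,000 records for parameter recovery; the acceptance script measures 10
regime corpora per invocation. The full suite completes in about half a
minute; the acceptance script in under ten seconds.

## Known limitations

* OvidSP parsing covers the filter-translation subset only: no `exp`
  explosion, subheadings, adjacency operators, or wildcards/truncation.
* `[tw]` omits PubMed's non-title/abstract/MeSH textword sources, and no
  automatic term mapping is emulated.
* Multi-comma inverted headings are not normalized.
* Terms containing bare boolean words (`and`, `or`, `not`) cannot be
  expressed, as the lexer treats them as operators.
* The generator's background text is token noise, not language; frequency
  analysis on real corpora will surface many more candidate phrases and
  lean correspondingly harder on the stoplist/blocklist curation step.
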