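# filterforge

Tools for extending a validated OvidSP Medline search filter to PubMed's
unique, non-indexed content.

## The problem

A *search filter* (or "hedge") is a pre-tested boolean strategy that
retrieves a topical slice of a bibliographic database — for example a
validated four-term heart failure filter built in OvidSP Medline.
Translating such a filter for PubMed is straightforward syntax conversion
(`.mp.` → `[tw]`, `/` → `[mh:noexp]`), but the translation inherits a blind
spot: PubMed's most recent citations (status `Publisher`/`In-Process`) have
no MeSH indexing yet, so any retrieval that relies on MeSH terms fails on
exactly the newest literature. Worse, a MeSH descriptor often is *not* the
phrase authors actually write: many records indexed with *Heart Failure*
never say "heart failure" in their title or abstract.

filterforge implements a reproducible five-phase method for quantifying and
repairing that blind spot, executable against local corpora in MEDLINE
tagged format (real `.nbib` exports or synthetic corpora with planted
ground truth):

1. **#1** — run the translated filter with terms acting on MeSH + textword
   fields (`[tw]`/`[mh:noexp]`), under study limits
   (`English[la] AND 2010[dp] AND "hasabstract" AND Medline[sb]`);
2. **#2** — rerun it with every term retagged to `[tiab]`;
3. **#3** — isolate the **Lost Set** `#1 NOT #2`: citations retrievable
   only through their indexing, and partition it into per-MeSH-term subsets;
4. discover high-frequency natural-language alternatives in each subset
   (frequency-ranked single terms, phrase-context n-grams, a frequency
   floor of 10, a subset-recall cutoff of 5%);
5. select the best-covering OR-combination of candidates by greedy maximum
   coverage over the full Lost Set, then assemble the final two-branch
   filter:

```
(validated translation AND Medline[sb])
  OR ((retagged terms OR selected terms, all [tiab]) NOT Medline[sb])
```

Because the branch restrictions are complementary, the supplementary
textword branch extends retrieval to non-indexed content without ever
changing what the validated filter retrieves from indexed content.

Intended users: information specialists and health-librarianship
researchers who build, translate and maintain search filters, and anyone
who wants a testbed for MeSH-vs-textword retrieval experiments.

## Worked example

Run the whole pipeline on a synthetic corpus generated in the heart-failure
study regime (3,000 records, 12% planted lost fraction, alternative phrases
planted at their observed conditional rates):

```python
from filterforge import PipelineConfig, run_pipeline
from filterforge import heart_failure as hf

config = PipelineConfig(
    filter_query=hf.FILTER_TERMS_TW,
    corpus_spec=hf.heart_failure_regime(seed=1),
    limits=hf.STUDY_LIMITS,
    blocklist=hf.DEFAULT_BLOCKLIST,
)
print(run_pipeline(config).to_text())
```

which prints:

```
filterforge 0.1.0 pipeline report
#1 (MeSH-empowered): 2507
#2 (textword-restricted): 2205 (overlap with #1: 2205)
#3 (Lost Set = #1 NOT #2): 302 (12.0% of #1)

Per-term subsets of the Lost Set:
  heart failure: 281 (93.0% of lost)
  left ventricular dysfunction: 20 (6.6% of lost)
  cardiomyopathy: 1 (0.3% of lost)

Candidate terms (phrase, subset, raw freq, record occurrence, subset %):
  cardiac failure	heart failure	29	29	10.3%
  cardiac resynchronization	heart failure	27	27	9.6%

Greedy selection trace:
  cardiac failure	+29	29/302	9.6%
  cardiac resynchronization	+26	55/302	18.2%

Assembled filter:
  ((heart failure[tw] OR left ventricular dysfunction[mh:noexp] OR cardiomyopathy[tw] OR left ventricular ejection fraction[tw]) AND Medline[sb]) OR ((heart failure[tiab] OR left ventricular dysfunction[tiab] OR cardiomyopathy[tiab] OR left ventricular ejection fraction[tiab] OR cardiac failure[tiab] OR cardiac resynchronization[tiab]) NOT Medline[sb])
```

Reading the numbers: of 2,507 citations retrieved through MeSH-empowered
searching, 302 (12.0%) vanish when the same strings are restricted to
titles/abstracts — the Lost Set. Frequency analysis of its heart-failure
subset surfaces two natural-language alternatives ("cardiac failure",
"cardiac resynchronization"), each retrieving ~10% of that subset; greedy
selection keeps both (marginal gains 29 and 26 lost citations) for a
combined reclaim of 18.2% of the Lost Set, and the assembled two-branch
filter embeds them in the supplementary `NOT Medline[sb]` branch.

The same stages are available as shell commands (`filterforge translate`,
`search`, `lostset`, `discover`, `select`, `assemble`, `simulate`, `run`);
see `filterforge --help`.

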