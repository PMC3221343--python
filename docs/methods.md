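# Methods

## Problem and scope

`evicite` profiles the references cited by point-of-care (POC) clinical
information products along four indicators: citation distribution, type of
evidence, currency, and cross-product overlap. It is a desk-scale,
metadata-driven analysis: the unit of observation is a bibliographic record
with MEDLINE indexing (publication types, MeSH), not the full text of the
cited article. The package deliberately does **not** appraise the
methodological quality of cited studies, score GRADE/Oxford evidence
levels, or fetch records from PubMed — inputs are local nbib/RIS files (or
synthetic corpora).

## Identity of a citation

Citations with a PMID are identified by it (`PMID:<digits>`). PMID-less
citations get a content-addressed identifier: a SHA-1 digest (first 16 hex
chars, scheme-versioned `v1`) of normalized title | year | first-author
surname; title-less web citations digest their normalized URL; records with
none of these fall back to source + product + ordinal and are flagged
unverified. Normalization is lowercase, punctuation stripped, whitespace
collapsed. The identifier is a pure function of record content, so the same
bibliographic content always maps to the same identity. Free-form date
strings ("2008 Jan-Feb") reduce to their first 4-digit year.

A record counts as *verified* when it has a title and either a year or a
PMID; unverified records (typically broken web links) are graded `unknown`.

## The classification protocol

Each record receives exactly one of nine categories by first-match
precedence:

| order | rule | category |
|---|---|---|
| 1 | not verified | unknown |
| 2 | guideline / practice-guideline / consensus types | guideline |
| 3a | Meta-Analysis (or modern Systematic Review) type | systematic_review |
| 3b | review-family type + systematic-conduct evidence | systematic_review |
| 4 | Randomized Controlled Trial type | randomized_controlled_trial |
| 5 | MeSH `Animals` without `Humans`, on a study-design type | animal_study |
| 6 | report source patterns (MMWR, government publications, statistical reports, technology assessments, task-force/working-group reports) or report types | report |
| 7 | remaining review-family types | review |
| 8 | letter/comment/editorial: reports study data → primary_research_other, else other | — |
| 9 | remaining study designs (case-control, cohort, cross-sectional, case series, unclear/combined — operationally: any remaining study-design type) | primary_research_other |
| 10 | books, abstracts, remaining non-research items | other |

The protocol is total and deterministic; permuting a record's
publication-type list never changes the outcome, and the rationale records
every rule that fired.

**Systematic-review promotion.** A full-text judgment of systematic conduct
is not reproducible at the desk, so it is operationalized as keyword
evidence in title+abstract: one term from each of three groups must be
present — search conduct ("we searched", MEDLINE/EMBASE/Cochrane, ...),
explicit selection ("inclusion criteria", "studies were included", ...),
and synthesis ("pooled", "meta-analysis", "random-effects", ...). The term
lists live in the `RuleSet` (YAML-serializable) so users can tighten or
loosen them; defaults were chosen to be specific rather than sensitive — a
narrative review mentioning a literature search does not qualify.

**Study-data detection** for letters/comments/editorials requires both
(1) a described or quantified sample (`n = ...`, "45 patients",
enrollment/cohort phrasing — always required) and (2) a structured-abstract
outline (≥ 2 distinct section-cue groups among
Objective/Introduction/Problem, Methods/Subjects, Results,
Discussion/Conclusion, matched as `Heading:`). Whether criterion 2 is
required is genuinely ambiguous; it defaults to required and is switchable
via `RuleSet.study_data_requires_structure`.

**Animal studies** are detected from MeSH (`Animals` present, `Humans`
absent) on study-design records, since publication types alone cannot
express "animal-only". **Synopses** (ACP Journal Club, FPIN items) are
MEDLINE-indexed as reviews; review-category outputs are flagged when their
source matches the synopsis pattern list, supporting an audit of the
synopsis share of the review category.

## Overlap matching

Matching is tiered: PMID-exact, then content-key exact (same normalized
title | year | surname; URL for title-less records), then an optional fuzzy
tier that merges pairs with normalized-title similarity ≥ 0.90
(`difflib.SequenceMatcher` ratio) and years within tolerance (default:
exact year). Clusters are the transitive closure of pairwise matches,
computed with a union-find; the fuzzy tier blocks candidate pairs by year
so the comparison count stays near-linear, and the result is proven (by
test) equal to an exhaustive all-pairs closure. Fuzzy matching is off by
default: PMIDs were collected precisely to make matching exact, and the
fuzzy tier exists for the PMID-less minority (web and book citations).

A cluster's multiplicity is the number of *distinct products* citing it; a
product citing the same work twice in one monograph counts once toward
multiplicity but both instances remain in `total_instances`, so the
conservation identity Σ k·n_k = total_instances holds exactly when no such
within-product duplicates exist (the synthetic generator never creates
them). Both summary conventions are emitted with labeled denominators:
percent of distinct citations, and percent of the instance pool (the
all-products cell at two decimals, the rest at one).

## Rounding

Table percentages round half-up (the convention of printed clinical
tables): one decimal everywhere, except the all-products overlap share at
two decimals and the synopsis share at integer precision. Column percent
sums are therefore allowed in [99.0, 101.0]. Currency denominators exclude
missing-year citations by default (they are observations missing from the
currency analysis), with a switch to include them.

## The synthetic generator

`CorpusSpec` fixes, per product: a 9-vector of category counts and a vector
of year-bin counts (both summing to the product total), plus the overlap
multiplicities {k → count}, a PMID-less fraction, a classification-noise
fraction, synopsis-source counts, and a seed. Generation is exact, not
sampled: product sets are assigned to shared clusters greedily
(largest-remaining-capacity first, seeded tie-breaks), shared clusters get
a category/year-bin available in every member product, and unique clusters
consume the remaining counts exactly — so the classifier and overlap stages
recover the spec's composition *identically*, not just in expectation.
Missing-year slots pair with unknown-category slots first, mirroring the
reality that the undatable citations are the unverifiable web links.

Record content is template-generated with controlled keyword insertion:
systematic reviews carry either a Meta-Analysis type or a Review type with
a search/selection/synthesis abstract; a fraction of primary research
records are letters with structured study abstracts; narrative reviews get
keyword-free prose; reports get report sources; titles are 7-word samples
(unique word sets) from a 170-word vocabulary, which keeps distinct titles
well below the 0.90 fuzzy threshold. Classification noise removes the
abstract and MeSH terms from a fraction p of citations, making them
*ambiguous* (e.g. a keyword-promoted systematic review falls back to
review) rather than steering them to a specific wrong class, so category
recovery is ≥ 1 − p by construction and 100% at p = 0.

What the generator does **not** emulate: real MEDLINE indexing variance
(multiple conflicting publication types beyond the templates), OCR/typo
noise in titles, within-product duplicate listings, monograph prose, or
the topic-selection procedure. Passing tests therefore demonstrate the
pipeline's correctness on records whose metadata is as informative as
MEDLINE's — not robustness to arbitrarily dirty bibliographies.

## The packaged study composition

`study_fixture()` encodes a five-product, four-topic study: per-product
evidence-type counts (totals 531 / 254 / 1131 / 153 / 261 = 2330), overlap
multiplicities {5: 2, 4: 4, 3: 25, 2: 161, 1: 1907} (2099 distinct), and
synopsis counts 18 + 1 + 1 among 286 reviews. Its currency profile fixes
the documented constraints — DynaMed 170/1131 in 2007–2009, Clinical
Evidence zero in 2007–2009, and one undatable web citation each in
Clinical Evidence and UpToDate — and fills the remaining bins with
deterministic values matching the qualitative pattern (pre-2001 is the
largest bin everywhere except FirstCONSULT, where 2001–2003 leads; the
2007–2009 bin is smallest). Those fills are package choices, not published
values, and per-topic breakdowns are seeded-random. Cluster-to-product
assignment of shared citations is likewise random under the seed, since
pairwise overlap is unconstrained.

## Problem sizes and runtime

The default test suite runs the full 2330-record composition once (shared
session fixture), 1000 small random specs for the conservation identity,
100 random corpora (≤ ~220 records) against the brute-force clustering
oracle, and 100 corpora of ~500 records for classifier recovery — about
half a minute on one CPU. The acceptance script runs the full composition
in a few seconds.

## Known limitations

- Systematic-review promotion and study-data detection are abstract-text
  surrogates for full-text judgment; on real corpora their error is
  governed by abstract quality, and the term lists should be reviewed per
  collection.
- RIS input carries no MEDLINE publication-type vocabulary; the documented
  `TY` mapping is coarse (e.g. `JOUR` → Journal Article) and classification
  of RIS-only corpora leans on `M3`/keyword fields.
- The greedy cluster-to-product assignment raises a validation error on
  overlap structures it cannot realize (e.g. more shared clusters than the
  smallest product can absorb); it does not search exhaustively.
- Fuzzy matching with `require_year_match=False` falls back to all-pairs
  comparison and is quadratic in corpus size.
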