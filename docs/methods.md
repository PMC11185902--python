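# Methods

## Problem setting

A Japanese medical NER system is applied, sentence by sentence, to
pharmaceutical care records written in SOAP format (subjective, objective,
assessment, plan, plus a free-text column). The system emits character-offset
disease/symptom spans with a positive/negative (P-N) polarity label — present
vs absent/ruled-out/not-yet-occurred. Human annotators produce gold spans
over the same sentences. `soapeval` scores the system against the gold
standard and decomposes the disagreement into an actionable error taxonomy.

## Preprocessing

**Cohort filter.** A record enters the evaluation when (a) at least one SOAP
section is non-blank (non-empty after whitespace stripping), (b) a cohort
keyword occurs as a substring of the raw free-text or objective section, and
(c) the record date lies within `[first dose, last dose + window]` of the
patient's dosing course (`window = 12` days by default). Keyword matching is
case-sensitive and happens *before* width normalization: the default keyword
list carries full-width and half-width katakana spellings of the drug plus
upper/lower-case Latin abbreviations as separate entries, which would be
redundant after normalization. Records of patients without a dosing course
are excluded with a logged warning, never silently.

**Normalization.** Every half-width katakana, ASCII letter, digit and symbol
is mapped to its full-width compatibility equivalent; half- and full-width
exclamation marks become the ideographic full stop 「。」 (the canonical
Japanese sentence terminator) so exclamations end sentences. The mapping is
one-to-one per character with one exception: a kana followed by a separate
voiced/semi-voiced sound mark composes into a single character (e.g. ｿﾞ → ゾ),
shrinking the text by one per pair. The function is idempotent, and offsets
are always counted in Unicode code points *after* normalization.

**Segmentation.** A sentence break is a line break or a period (。 or ．).
Delimiters attach to the preceding sentence; empty or whitespace-only
segments are dropped without reassigning their character range, so surviving
sentences' `[char_start, char_end)` offsets always index the section text and
concatenation reconstructs it exactly.

## Span matching

Within one sentence, gold and system spans are aligned one-to-one over
edges defined by ≥ 1 character of overlap. The counting rule — matched terms
are tallied in the units that *minimize* the matched-term total when one span
overlaps several on the other side — is realized as maximum-cardinality
bipartite matching: in every star configuration (one span against k ≥ 2) the
maximum one-to-one assignment yields exactly min(1, k) = 1 matched term,
which is the smaller unit count. Among maximum-cardinality assignments the
implementation prefers the one with the most exact-boundary pairs (so a
boundary-perfect extraction is never reported as partial), and breaks
remaining ties leftmost-first. The assignment is computed by
`scipy.optimize.linear_sum_assignment` over tiered integer weights
(cardinality ≫ exact bonus ≫ positional tie-break), and is checked in the
test suite against an independent exhaustive-enumeration oracle on random
sentences with up to 8 spans per side.

Two structural facts simplify the rules. First, because spans from one source
never overlap each other, two candidate pairs can never cross: if gold
g₁ < g₂ and system s₁ < s₂, then g₁ overlapping s₂ forces g₁.end > s₂.start ≥
s₁.end ≥ g₂.start's lower bound, contradicting g₂ overlapping s₁. Repeated
identical surfaces in one sentence are therefore paired order-preservingly by
*any* one-to-one overlap assignment — the positional-relationship requirement
holds by construction. Second, an exact edge is vertex-exclusive (any other
span overlapping one endpoint would overlap its twin), so exact pairs can
never be displaced by partial ones; the exact-preference tier is retained as
a safeguard.

Polarity agreement is recorded per pair but never influences the assignment:
P-N classification is evaluated on already-matched extractions. A matched
pair with discordant polarity counts at the NER level but not at the
NER + P-N level.

## Metrics

Precision, recall and F1 follow the standard formulas with TP the matched
count, FP = n_system − TP, FN = n_gold − TP, and the convention that each
metric is 0 on an empty denominator. The pooled "all" row is the
component-wise sum of the four section count columns. Display rounding is
half-up to two decimals, switching to two significant figures below 0.095 so
small proportions (e.g. 0.054, 0.077) survive printing; all reports carry raw
and rounded values side by side.

Per-record summaries use the sample SD (n − 1 denominator, the clinical
reporting convention; 0.0 is reported for a single record, where the sample
SD is undefined). The extraction fraction is mean(matched)/mean(gold) and the
classification fraction mean(polarity-concordant)/mean(matched).

Cohen's κ is computed from any square agreement table; the unit of analysis
is deliberately left to the caller, since reasonable choices (candidate
terms, sentences, term + polarity judgments) differ and the operation is
unit-agnostic. The degenerate single-category table returns κ = 1. The
implementation is cross-checked against scikit-learn in the tests.

The sample-size operation uses the exact normal quantile (1.959964 for 95%)
and a ceiling, since a sample size must guarantee the stated half-width.

## Error taxonomy

Within each sentence the bipartite overlap graph (all ≥ 1-character edges,
not just assigned pairs) is decomposed into connected components:

* **Category 1** (system extraction failure): gold spans with no edge.
* **Category 2** (incorrect extraction): system spans with no edge.
* **Category 3** (P-N difference): per component, the number of gold spans
  with a polarity-discordant edge or the number of such system spans,
  whichever is *larger* — mismatches are counted in the unit that increases
  the mismatch total.
* **Category 4** (length difference): likewise with non-exact-boundary
  edges; partial matches count as matches for categories 1–3 but as
  mismatches for category 4, so categories 3 and 4 are not mutually
  exclusive and percentages need not sum to 100%.

Percentages divide by the total extracted terms
`n_system + n_gold − n_matched`. When the overlap graph is itself one-to-one
these definitions collapse to closed-form identities
(cat1 = n_gold − matched, cat2 = n_system − matched,
cat3 = matched_ner − matched_pn, cat4 = number of partial pairs), which the
tests verify on synthetic corpora. The per-component max(gold-side,
system-side) reading is an interpretation: it is the only one under which
star configurations can push a category count above the one-to-one identity,
and it reduces to that identity everywhere else.

Subcategory tagging (e.g. "verbs, adjectives and adverbs", "item names") is a
configurable rule engine over the categorized terms — exact-lexicon
membership, surface regex, and sentence-context regex, optionally restricted
to one cause category; a term may satisfy several rules. It deliberately does
not attempt part-of-speech tagging, which would require a morphological
analyzer; the shipped default rules are a starter set, not a reimplementation
of human linguistic judgment.

## Synthetic corpus generator

The generator emulates the *structure* of a pharmacist-record corpus, not its
language: sentences are lexicon surfaces (Japanese disease/symptom terms)
separated by filler characters and terminated by 。, so matching, metrics and
taxonomy — which depend only on offsets, surfaces, polarities and
delimiters — are exercised faithfully, while nothing about natural Japanese
syntax is simulated. Conclusions about linguistic phenomena (morphology,
colloquialisms, context-dependent polarity) therefore cannot be drawn from
passing tests; conclusions about the counting and scoring machinery can.

Per-section profiles fix the sentence-count and sentence-length
distributions (Poisson around the section medians, clipped to observed
ranges: subjective 4 sentences / 18 chars, objective 37 / 29, assessment
4.5 / 15, plan 2 / 10), the gold-entity rate per sentence, and four error
rates applied to derive the system annotation from the gold standard:

| knob | action | induced error |
|---|---|---|
| `p_fn` | delete a gold span | category 1 |
| `p_fp` | insert a spurious span (per sentence) | category 2 |
| `p_flip` | flip a surviving span's polarity | category 3 |
| `p_boundary` | shift a surviving span's boundaries | category 4 |

Boundary shifts are uniform over all variants within ±`boundary_shift_max`
(default 2) characters that stay inside the sentence, keep ≥ 1 character of
overlap with the original, avoid neighbouring spans, and actually change the
span. Spurious spans are 2–4 character substrings placed in regions disjoint
from every existing span by default, which keeps the overlap graph exactly
one-to-one so that the truth log predicts every downstream count
(`expected_counts`); a flag allows overlapping spurious spans to exercise the
matching tie-breaks, at the cost of that exactness. All draws flow from one
seeded NumPy generator in documented order (sentence layout, then per-span
deletion, flip, shift, then per-sentence spurious insertion), so equal seeds
give identical corpora.

The default per-section error rates are calibrated once to the study
structure the package targets (high subjective miss rate ≈ 0.68, high plan
spurious rate, low assessment spurious rate), so a default run qualitatively
reproduces the characteristic performance ordering assessment > objective >
subjective > plan at both evaluation levels.

`recover_parameters` inverts the injection model from the downstream
evaluation alone — p̂_fn = cat1/n_gold, p̂_flip = cat3/matched, p̂_boundary =
cat4/matched, with cat2/n_system as the precision-loss summary of `p_fp` —
and the acceptance suite requires each estimate to land within 3 binomial
standard errors of the generating value on corpora of ≥ 2000 gold spans
across ten seeds.

## Problem sizes and numerical choices

The test suite runs the matching oracle on 400 random sentences (≤ 8 spans a
side, exhaustive enumeration), parameter recovery on ten 170-record corpora
(≈ 2100 gold spans each), and the full metric grid from count tables; the
whole suite completes in well under a minute on one CPU. Assignment weights
are integers sized so the three tiers cannot interact for any realistic
sentence. Degenerate inputs are defined rather than erroneous wherever a
convention exists (empty denominators → 0, single-record SD → 0, empty span
sets → empty match result); genuinely contradictory inputs (overlapping
same-source spans, spans off their sentence, duplicate record ids,
overlapping aggregation scopes) raise validation errors naming the offender.

## Known limitations

* Sentence text is template-generated; no morphological or contextual realism.
* The κ unit of analysis is not prescribed, so a specific published κ value
  can only be reproduced given the same unit definition.
* The per-component maximizing-unit rule for categories 3–4 is an
  interpretation of an under-specified convention (documented above).
* No overlap-fraction thresholds other than ≥ 1 character, no concept-level
  (dictionary-coded) matching, and no weighted κ or bootstrap intervals.
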