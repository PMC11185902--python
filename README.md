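# soapeval

Span-level evaluation of clinical named-entity recognition (NER) with
positive–negative (P-N) polarity on SOAP-format pharmaceutical care records.

Pharmacists document patient contacts in records with subjective / objective /
assessment / plan (SOAP) sections plus a free-text column. When a Japanese
medical NER system (such as MedNER-J) is applied to these records to extract
disease and symptom mentions, its output must be scored against human
annotation under conventions that differ from ordinary NER benchmarks:
matching is per sentence and character-based (a *partial* match is any
overlap of ≥ 1 character; an *exact* match has identical boundaries), repeated
identical surfaces must be paired by position, and when one span on one side
overlaps several on the other, matched terms are counted in the units that
minimize the matched-term total. `soapeval` implements this evaluation
end-to-end for anyone scoring NER output on SOAP-structured clinical text:

* **records** — SOAP record data model, cohort inclusion filtering
  (keyword + dosing-window), half-to-full-width normalization, and sentence
  segmentation at line breaks and periods with exact offset bookkeeping;
* **span_matching** — exact/partial one-to-one span alignment via
  maximum-cardinality bipartite assignment, with standoff-TSV and inline-XML
  annotation ingestion;
* **metrics_agreement** — precision / recall / F1 per section and overall at
  two levels (NER alone, NER + P-N), per-record summaries, Cohen's κ, and the
  proportion sample-size formula;
* **error_taxonomy** — the four mismatch cause categories (system extraction
  failure, incorrect extraction, P-N difference, length difference) with
  their asymmetric counting conventions, plus a configurable subcategory rule
  engine;
* **synthetic_corpus** — a seeded generator of SOAP-structured corpora with
  gold annotations and an error-injection model (deletions, spurious spans,
  polarity flips, boundary shifts), so the whole pipeline is testable without
  confidential hospital records.

## The statistics at the core

With TP the matched-term count, FP the system surplus and FN the gold surplus
for a section,

```
precision = TP / (TP + FP)     recall = TP / (TP + FN)     F1 = 2PR / (P + R)
```

At the NER level a true positive is any exact or partial alignment; at the
NER + P-N level the pair must also agree in polarity. Mismatch percentages
are taken over the *total extracted terms* `n_system + n_gold − n_matched`.
Inter-annotator validity uses Cohen's `κ = (p_o − p_e) / (1 − p_e)`, and the
sample size to estimate a proportion `p` within `±m` at confidence `1 − α` is
`⌈z² p(1−p) / m²⌉`.

## Worked example

Generate a synthetic 60-record corpus with the default error-injection
profile and evaluate it:

```bash
soapeval simulate --seed 7 --n-records 60 --out-dir demo
soapeval evaluate --records demo/records.jsonl --gold demo/gold.tsv \
    --system demo/system.tsv --dosing demo/dosing.csv --out-dir demo/out
```

prints (display-rounded):

```
      level    section  n_system  n_gold  n_matched  precision  recall    f1
   ner_only subjective        54     138         44      0.810    0.32 0.460
   ner_only  objective       387     407        281      0.730    0.69 0.710
   ner_only assessment       131     206        131      1.000    0.64 0.780
   ner_only       plan        30      18          9      0.300    0.50 0.370
   ner_only        all       602     769        465      0.770    0.60 0.680
ner_plus_pn subjective        54     138         24      0.440    0.17 0.250
ner_plus_pn  objective       387     407        153      0.400    0.38 0.390
ner_plus_pn assessment       131     206        106      0.810    0.51 0.630
ner_plus_pn       plan        30      18          2      0.067    0.11 0.083
ner_plus_pn        all       602     769        285      0.470    0.37 0.420
```

Each row gives the system/gold/matched term counts for one SOAP section and
the resulting precision, recall and F1; the `ner_plus_pn` block additionally
requires polarity agreement, so its metrics are never higher. With the
default profile the F1 ordering assessment > objective > subjective > plan
emerges from the injected per-section error rates. `demo/out/` receives the
count, metric and error-category tables as CSV plus a `report.json` bundle
carrying both raw and display-rounded values.

The counts-only mode recomputes the metric table from a per-section count
table alone (columns `section, n_system, n_gold, n_matched_ner,
n_matched_pn`):

```bash
soapeval metrics --counts counts.csv --out report.csv
```

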