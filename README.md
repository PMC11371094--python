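# mmstage

Rule-based extraction of **multiple myeloma (MM) stage** from free-text
clinical notes, with aggregation to a per-patient stage at treatment
initiation.

MM stage is a core measure of disease risk, but it is rarely available as
structured data: its inputs (beta-2 microglobulin, albumin, LDH,
cytogenetics, marrow findings) are scattered or externally measured, so
registries and claims data mostly lack it. Oncologists, however, routinely
*write* the stage in their notes — "ISS stage III", "R-ISS 2",
"Durie-Salmon IIIA", or just "stage II myeloma". `mmstage` reads that
documentation back out, for researchers who need stage as a covariate in
retrospective cohorts built from EHR note text.

## What it does

1. **Snippet construction** (`snippet_finder`) — a broad case-insensitive
   trigger set (`stage`/`staging`, `ISS`, `R-ISS`, `Durie`, `DS`, `D-S`)
   marks candidate mentions; a window of 100 characters before and 200
   after each match becomes a *snippet*.
2. **Snippet-level extraction** (`stage_nlp`) — ordered regex rules label
   spans (stage values, staging systems, myeloma mentions, other staged
   diseases, antibiotic names), resolve same-category overlaps by rule
   priority, suppress stage values near other diseases ("CKD stage 3") and
   DS system tokens near antibiotics ("Bactrim DS"), then associate each
   surviving value with the nearest system within 40 characters. The
   output per snippet is a set of labels (*system*, *value*) with
   *system* ∈ {R-ISS, ISS, DS, UNCLEAR} and *value* ∈ {1, 2, 3}; an
   empty set means "not stage". A value with no nearby system is UNCLEAR;
   subclass letters (DS IIIA/IIIB) are collapsed; ranges ("stage II–III")
   expand to both values.
3. **Patient-level roll-up** (`patient_rollup`) — keep hematology/oncology
   notes and pathology reports within ±365 days of the treatment-initiation
   index date; independently per system, assign the value from the note
   closest to the index date.
4. **Evaluation** (`evaluation`) — per-system contingency tables over units
   (snippets or patients): TP if predicted set = gold set ≠ ∅, TN if both
   empty, FP for any spurious value, FN for a missed value (FP-dominant, so
   cells sum to the unit count). Precision = TP/(TP+FP),
   recall = TP/(TP+FN), F1 their harmonic mean, reported half-up at two
   decimals with exact rationals kept internally.
5. **Synthetic corpus** (`synthetic_corpus`) — real staging corpora are
   restricted EHR data, so a seeded generator produces notes, snippet-level
   gold, and patient-level gold that exercise every rule family without any
   data download.

## Worked example

```python
>>> from mmstage import extract_text_stage
>>> sorted((l.system.value, l.value) for l in extract_text_stage(
...     "Staging notable for R-ISS 2 and ISS 3."))
[('ISS', 3), ('RISS', 2)]
>>> extract_text_stage("Bactrim DS 800-160 bid for prophylaxis.")
frozenset()
```

The first call finds two named-system labels in one sentence — each stage
value is associated with its own nearest system. The second returns the
empty set: "DS" next to an antibiotic name is a drug strength, not a
Durie-Salmon mention, so the snippet is "not stage".

The `examples/` directory has one short script per capability
(`python examples/01_extract_stage.py`, ...): single-sentence extraction,
snippet windowing, patient roll-up, evaluation, and an end-to-end run on a
synthetic corpus. The last one prints, for 50 simulated patients, a
per-system patient-level report —

```
  level  system  tp  tn  fp  fn  precision  recall  f1
patient    RISS  14  36   0   0        1.0     1.0 1.0
patient     ISS  19  31   0   0        1.0     1.0 1.0
patient      DS  15  35   0   0        1.0     1.0 1.0
patient UNCLEAR  13  37   0   0        1.0     1.0 1.0
```

— meaning extraction plus roll-up recovered every simulated patient's
per-system stage at the index date from raw note text.

A CLI mirrors the library, one thin subcommand per stage:

```bash
mmstage simulate --out data/ --seed 7 --n-patients 200
mmstage snippets --notes data/notes.jsonl --out snips.jsonl
mmstage extract  --snippets snips.jsonl --out preds.jsonl
mmstage rollup   --predictions preds.jsonl --snippets snips.jsonl \
                 --notes data/notes.jsonl --index-dates data/index_dates.jsonl \
                 --out patient_stage.jsonl
mmstage evaluate --pred patient_stage.jsonl --gold data/patient_gold.jsonl \
                 --level patient --out report.csv
```

All formats are JSONL (schemas documented in `mmstage/corpus_io.py`); rules
are editable YAML (`mmstage dump-rules --out rules.yaml`).

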