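# Methods

## Problem setting

Multiple myeloma stage has been documented under three systems — the
Revised International Staging System (R-ISS), the International Staging
System (ISS), and Durie-Salmon (DS) — each with stages I–III (DS adds
subclasses A/B, collapsed here because they encode renal function rather
than a distinct stage level). Clinicians also frequently write a bare
stage value with no system named ("stage II myeloma"); such mentions are
kept as a fourth category, UNCLEAR, rather than guessed into a system. The
atomic extraction output is therefore a set of (system, value) labels with
system ∈ {RISS, ISS, DS, UNCLEAR} and value ∈ {1, 2, 3}; the empty set
encodes "not stage". One convention runs through annotation, extraction
and roll-up alike: when a snippet documents both a named-system stage and
a systemless stage, only the named system is kept (clear-over-unclear).

## Snippet construction

Candidate mentions are found by a deliberately broad case-insensitive
trigger set — the words `stage`/`staging` (with plural/participle
suffixes), `ISS`, `R-ISS`/`RISS`, `Durie`, `Durie-Salmon`, `DS`, `D-S` —
and a window of **100 characters before / 200 after** each trigger is cut
as a snippet. Over-generation is intended: precision is the job of the
downstream rules, so the trigger set only has to be high-recall.
Overlapping triggers ("ISS" inside "R-ISS") resolve leftmost-longest,
implemented by ordering alternation branches longest-first; an independent
position-by-position scan oracle checks this in the tests. One snippet is
emitted per trigger even when windows overlap; offsets are 0-based,
half-open, in Unicode characters. The original system's exact trigger
regex is not public; the shipped set is this package's own and is config
(`SnippetWindowConfig`), as are the window sizes.

## Snippet-level extraction

Four stages, in order; all thresholds and lexicons live in a YAML-round-
trippable `RuleSet`, reflecting the iterate-on-rules workflow this kind of
system is built by.

**Span labeling.** Ordered regexes emit five span categories: stage
values, staging systems, myeloma mentions, *other-disease* mentions
(chronic kidney disease/CKD, generic cancer/carcinoma/lymphoma/…, heart
failure, COPD, pressure ulcers — diseases whose own stage appears in
oncology notes), and antibiotic names (Bactrim, Septra,
trimethoprim-sulfamethoxazole, TMP-SMX…) whose "DS" (double-strength)
suffix shadows the Durie-Salmon abbreviation. A design choice worth
stating: a numeral or roman numeral is only labeled a stage value in an
anchoring context — after `stage`/`staging` or adjacent to a system name —
because without an anchor every stray "I" or "2" in prose would surface as
an UNCLEAR label. The anchor is part of the value rule's regex context;
the span itself covers only the value.

**Normalization.** Roman I/II/III (any case) and arabic 1/2/3 map to
1/2/3; a trailing A/B subclass letter is stripped first; anything else
(IV, 4, 0) is rejected as a value, not an exception. System variants map
to canonical names ("International Staging System" → ISS, "Revised ISS" →
RISS, "Durie/Salmon" → DS, …). Hyphen/slash ranges ("II-III", "2/3")
expand to both endpoint values.

**Overlap resolution.** Among same-category spans that overlap, the span
from the earliest rule survives (ties: leftmost, then longest); this is
what makes "R-ISS" beat the "ISS" contained in it. Cross-category overlaps
are retained. The tests characterize the survivor set by its fixed-point
properties (no surviving same-category overlap; every dropped span
overlaps a surviving better one) rather than re-running the algorithm.

**Context suppression.** Stage values within **50 characters**
(nearest-edge distance) of an other-disease span are discarded; DS system
spans within 50 characters of an antibiotic are discarded. Additionally, a
*bare* DS/D-S token is only accepted as a staging system when a myeloma
mention or a stage value lies within the association window — a
stricter-than-necessary guard that buys precision on a highly ambiguous
token at no observed recall cost on the fixture suite.

**Association.** Each surviving value links to a system within **40
characters**, preferring (in order) a system connected by connective
material only ("by", "per", "stage", articles, punctuation), the smallest
gap, a preceding system, the leftmost. No candidate → UNCLEAR. The final
set is deduplicated and the clear-over-unclear rule applied. The 50- and
40-character windows and the connective list are this package's own
defaults (the original system's supplement-only values are unavailable);
they are exposed in `RuleSet` precisely so they can be re-tuned against
local data.

Known limitation: association is proximity-based, so a systemless value
within 40 characters of an unrelated system mention can be attributed to
it ("ISS stage III, previously stage 2" reads the 2 as ISS). No negation
handling is attempted, and laboratory values are never interpreted — only
language about the staging systems themselves.

## Patient-level roll-up

Only hematology/oncology notes and pathology reports within ±365 days
(inclusive) of the treatment-initiation index date are considered; the
window is plain day arithmetic. Independently per system, the value from
the note closest to the index date wins. Tie rules, fully deterministic:
equidistant notes prefer the one on or before the index date (initial
staging precedes treatment more often than restaging follows it within
days; configurable), then the lexicographically earlier note id; two
values for one system in one note resolve to the label whose provenance
span starts earliest in the note. UNCLEAR is populated only from
UNCLEAR-labeled snippets; a patient whose filtered notes carry no labels
at all has no assignments and is flagged missing. A separate optional
post-processing step (`apply_system_preference`, CLI `--prefer
riss,iss,ds`) picks a single preferred system per patient for downstream
hierarchies; it is off by default because the roll-up proper makes no
cross-system choices.

## Evaluation

Unit-level exact-set matching per system, because the published validation
tables count snippets and patients, not mentions. Per unit: TP if
predicted = gold ≠ ∅, TN if both empty, FP if any spurious value, FN if a
value was missed and the unit is not already FP. FP-dominance for
mixed-error units is forced by the requirement that cells sum to the unit
count (the published rows do: e.g. 204+832+2+3 = 1,041). Metrics are exact
`Fraction`s internally; reported values round half-up to two decimals,
which reproduces every published precision/recall/F1 cell derivable from
the printed counts except one patient-level DS F1 (printed 0.92 where the
cells give 0.9268 → 0.93; that cell's derivation is unclear at the source,
and it is reported here as computed). Undefined metrics (zero denominator)
are flagged `None`, never 0. The dev/val split is a seeded shuffle with
`floor(val_fraction·N)` validation ids — 5,207 ids at 20% give 4,166/1,041.
An independent cross-check against scikit-learn's metrics on random tables
guards the formulas.

## Synthetic corpus generator

The generator emulates the data environment the pipeline targets: per
patient, an index date and 2–8 notes dated uniformly within ±540 days of
it (so the ±365-day filter has work to do), typed HEM_ONC/PATHOLOGY/OTHER
at 60/15/25% (so the type filter has work to do). Each note carries a
staging sentence with probability 0.6 — system mix RISS/ISS/DS/UNCLEAR =
25/30/20/25%, value mix 1/2/3 = 30/35/35%, 10% two-system sentences — and
a distractor sentence (CKD stage, other-cancer stage, Bactrim DS) with
probability 0.3. These defaults are this package's choice of a realistic
treated-myeloma note stream: named systems dominate but a quarter of
documentation names no system, stage 1 is somewhat rarer at treatment
initiation, and DS reflects legacy-era notes. Surface forms (roman/arabic,
DS subclass letters, system spellings) are randomized per render.

Gold is computed from the template slots at generation time, never by
running the extractor, so extractor tests against it are not circular.
Patient-level gold is derived from the generated mentions by the same
documented closest-note rule the roll-up implements — the
generator-consistency invariant (roll-up of snippet gold reproduces
patient gold, any seed) is a genuine test of the roll-up because the two
implementations share only the rule statement. Distractor sentences are
separated from true mentions by ≥60 characters of filler so suppression
cannot cross sentences accidentally; deliberate same-window collisions are
covered instead by hand-labeled "hard" fixture cases. Filler prose comes
from a seeded neutral word pool free of trigger tokens; no real clinical
text is embedded anywhere.

What passing on this corpus does *not* show: robustness to real clinical
language — section headers, tables, negation, misspellings, local
abbreviations. The fixture suite (≥60 rendered cases across every system ×
value × surface form × distractor family) fixes the behavior of every rule
family; real-data performance requires local validation and likely local
rule edits, which is why every lexicon and window is config.

## Numerical and procedural choices

- Problem sizes in tests and the acceptance script (200 oracle patients,
  10 consistency seeds, 25–40 patients per seeded corpus check) are chosen
  to exercise every tie and filter path with comfortable margin while
  keeping the full suite in seconds.
- All randomness flows from explicit integer seeds through
  `random.Random`; outputs are byte-identical across runs and platforms.
- Dates are ISO-8601 days; no times, no time zones.
- JSONL is canonical on disk (free text with newlines is fragile in CSV);
  CSV is accepted for notes only.
- Readers fail loudly with file:line on malformed records and never drop
  records silently; unknown note types map to OTHER with a logged warning
  since note-title vocabularies are site-specific (a config mapping
  translates local titles to HEM_ONC/PATHOLOGY/OTHER).
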