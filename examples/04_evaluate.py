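"""Score predictions against gold with per-system contingency tables.

Also recomputes precision/recall/F1 from a published validation contingency
row to show the metric conventions (exact rationals, half-up rounding).
"""

from mmstage import ContingencyTable, StageLabel, StagingSystem, compute_metrics, evaluate_corpus

lbl = lambda s, v: StageLabel(StagingSystem[s], v)

gold = {
    "s1": {lbl("ISS", 3)},
    "s2": {lbl("RISS", 1)},
    "s3": set(),                 # "not stage"
    "s4": {lbl("UNCLEAR", 2)},
}
pred = {
    "s1": {lbl("ISS", 3)},       # exact match        -> ISS TP
    "s2": set(),                 # missed             -> RISS FN
    "s3": {lbl("DS", 2)},        # spurious           -> DS FP
    "s4": {lbl("UNCLEAR", 2)},   # exact match        -> UNCLEAR TP
}

report = evaluate_corpus(pred, gold, level="snippet")
print(report.to_string(index=False))
print()

# Published snippet-level validation row for R-ISS: TP=204 TN=832 FP=2 FN=3
metrics = compute_metrics(ContingencyTable(StagingSystem.RISS, tp=204, tn=832, fp=2, fn=3))
print(f"R-ISS validation row: precision={metrics.precision} "
      f"recall={metrics.recall} f1={metrics.f1}")
# Cells in each row sum to the number of evaluated units; a unit with both a
# spurious and a missed value counts once, as FP.
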