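"""Per-system contingency tables, precision/recall/F1, and the dev/val split.

Scoring is unit-level (snippet or patient) with exact-set matching per
staging system.  For each unit, with P the predicted stage values for the
system and G the gold values:

* TP — P = G and both non-empty
* TN — P = G = ∅
* FP — P contains a value not in G (counted once per unit; a unit with both
  a spurious and a missed value counts as FP only, so cells always sum to
  the number of units)
* FN — G contains a value not in P, and the unit is not already FP

Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;
exact rationals are kept internally and reported values are rounded
half-up (default 2 decimals).  A zero denominator flags the metric
undefined rather than zero.
"""

from __future__ import annotations

import decimal
import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import StageLabel, StagingSystem

REPORTED_SYSTEMS = (
    StagingSystem.RISS,
    StagingSystem.ISS,
    StagingSystem.DS,
    StagingSystem.UNCLEAR,
)


@dataclass(frozen=True)
class ContingencyTable:
    """TP/TN/FP/FN counts for one staging system over a set of units."""

    system: StagingSystem
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for cell in (self.tp, self.tn, self.fp, self.fn):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")

    @property
    def n_units(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _round_half_up(x: Fraction, ndigits: int) -> float:
    d = decimal.Decimal(x.numerator) / decimal.Decimal(x.denominator)
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricSet:
    """Precision/recall/F1 with undefined-denominator flags.

    ``precision``/``recall``/``f1`` are the rounded reported values (None
    when undefined); the ``*_exact`` fields keep the exact rationals.
    """

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    precision_exact: Optional[Fraction]
    recall_exact: Optional[Fraction]
    f1_exact: Optional[Fraction]
    rounding: int = 2


def compute_metrics(table: ContingencyTable, rounding: int = 2) -> MetricSet:
    """Precision, recall and F1 from one contingency table.

    F1 is computed from the exact (unrounded) precision and recall, then
    rounded for reporting.
    """
    precision = Fraction(table.tp, table.tp + table.fp) if table.tp + table.fp else None
    recall = Fraction(table.tp, table.tp + table.fn) if table.tp + table.fn else None
    f1 = None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = Fraction(0)
    return MetricSet(
        precision=_round_half_up(precision, rounding) if precision is not None else None,
        recall=_round_half_up(recall, rounding) if recall is not None else None,
        f1=_round_half_up(f1, rounding) if f1 is not None else None,
        precision_exact=precision,
        recall_exact=recall,
        f1_exact=f1,
        rounding=rounding,
    )


def _values_for(labels: Iterable[StageLabel], system: StagingSystem) -> Set[int]:
    return {l.value for l in labels if l.system is system}


def build_contingency(
    predictions: Mapping[str, Iterable[StageLabel]],
    gold: Mapping[str, Iterable[StageLabel]],
    system: StagingSystem,
) -> ContingencyTable:
    """Count TP/TN/FP/FN for one system over units keyed by id.

    Predictions and gold must cover exactly the same unit ids.
    """
    if set(predictions) != set(gold):
        missing = set(gold) ^ set(predictions)
        raise ValueError(f"unit ids differ between predictions and gold: {sorted(missing)[:5]}")
    tp = tn = fp = fn = 0
    for unit_id in predictions:
        p = _values_for(predictions[unit_id], system)
        g = _values_for(gold[unit_id], system)
        if p == g:
            if p:
                tp += 1
            else:
                tn += 1
        elif p - g:
            fp += 1
        else:
            fn += 1
    return ContingencyTable(system, tp, tn, fp, fn)


def evaluate_corpus(
    predictions: Mapping[str, Iterable[StageLabel]],
    gold: Mapping[str, Iterable[StageLabel]],
    level: str = "snippet",
    group_by: Optional[Mapping[str, str]] = None,
    rounding: int = 2,
) -> pd.DataFrame:
    """Per-system evaluation report; one row per system (per group).

    ``group_by`` optionally maps unit id to a group value (e.g. region),
    in which case rows are repeated per group.
    """
    if level not in ("snippet", "patient"):
        raise ValueError(f"level must be 'snippet' or 'patient', got {level!r}")
    if not gold:
        raise ValueError("nothing to evaluate: empty unit set")

    def rows_for(pred_subset, gold_subset, group):
        for system in REPORTED_SYSTEMS:
            table = build_contingency(pred_subset, gold_subset, system)
            metrics = compute_metrics(table, rounding)
            row = {
                "level": level,
                "system": system.value,
                "tp": table.tp,
                "tn": table.tn,
                "fp": table.fp,
                "fn": table.fn,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
            }
            if group is not None:
                row["group"] = group
            yield row

    rows: List[dict] = []
    if group_by is None:
        rows.extend(rows_for(predictions, gold, None))
    else:
        for group in sorted(set(group_by.values())):
            ids = [u for u in gold if group_by.get(u) == group]
            rows.extend(
                rows_for(
                    {u: predictions[u] for u in ids},
                    {u: gold[u] for u in ids},
                    group,
                )
            )
    return pd.DataFrame(rows)


def split_dev_val(
    unit_ids: Sequence[str], val_fraction: float, seed: int
) -> Tuple[List[str], List[str]]:
    """Seeded random split into development and validation id lists.

    The validation set gets ``floor(val_fraction * N)`` ids; the remainder is
    development.  The same seed always yields the same partition.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    ids = list(unit_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("unit ids must be distinct")
    if not ids:
        return [], []
    rng = random.Random(seed)
    rng.shuffle(ids)
    n_val = int(val_fraction * len(ids))
    return sorted(ids[n_val:]), sorted(ids[:n_val])
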