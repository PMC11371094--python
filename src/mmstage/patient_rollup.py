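"""Patient-level stage assignment at the treatment-initiation index date.

Each patient typically has many stage-bearing snippets spread over years of
notes.  For downstream use a single stage per staging system is wanted at the
index date (treatment initiation).  The roll-up:

1. keeps only hematology/oncology notes and pathology reports dated within a
   window (default ±365 days, inclusive) of the index date;
2. independently for each system (R-ISS, ISS, DS, UNCLEAR) assigns the value
   from the snippet whose note date is closest to the index date.

Equidistant ties default to the note on or before the index date (initial
staging precedes treatment more often than restaging follows it within
days), then to the lexicographically earlier note id.  When one chosen note
carries two different values for a system, the label whose provenance span
starts earliest in the note wins.  A patient with no stage-bearing snippet
in the filtered notes has no assignments and is flagged missing.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .models import (
    ClinicalNote,
    NoteType,
    PatientAnnotation,
    SnippetPrediction,
    StageLabel,
    StagingSystem,
)
from .snippet_finder import Snippet


class TieBreak(str, Enum):
    PREFER_ON_OR_BEFORE = "PREFER_ON_OR_BEFORE"
    PREFER_AFTER = "PREFER_AFTER"


@dataclass(frozen=True)
class RollupConfig:
    """Note filters and tie rules for the roll-up."""

    window_days: int = 365
    eligible_note_types: frozenset = frozenset({NoteType.HEM_ONC, NoteType.PATHOLOGY})
    tie_break: TieBreak = TieBreak.PREFER_ON_OR_BEFORE

    def __post_init__(self) -> None:
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        types = frozenset(NoteType(t) for t in self.eligible_note_types)
        if not types:
            raise ValueError("eligible_note_types must be non-empty")
        object.__setattr__(self, "eligible_note_types", types)
        object.__setattr__(self, "tie_break", TieBreak(self.tie_break))


@dataclass(frozen=True)
class StageAssignment:
    """One per-system assignment with source-note provenance."""

    system: StagingSystem
    value: int
    source_note_id: str
    source_note_date: _dt.date
    day_distance: int


@dataclass(frozen=True)
class PatientStageRecord:
    """Per-system stage assignments for one patient at an index date."""

    patient_id: str
    index_date: _dt.date
    assignments: Mapping[StagingSystem, StageAssignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def missing(self) -> bool:
        return not self.assignments

    def to_annotation(self) -> PatientAnnotation:
        """Collapse to the annotation shape (per-system values only)."""
        return PatientAnnotation(
            self.patient_id,
            self.index_date,
            {s: a.value for s, a in self.assignments.items()},
        )

    def to_obj(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "index_date": self.index_date.isoformat(),
            "per_system": {s.value: a.value for s, a in sorted(self.assignments.items())},
            "missing": self.missing,
            "provenance": {
                s.value: {
                    "note_id": a.source_note_id,
                    "note_date": a.source_note_date.isoformat(),
                    "day_distance": a.day_distance,
                }
                for s, a in sorted(self.assignments.items())
            },
        }


def select_notes(
    notes: Iterable[ClinicalNote],
    index_date: _dt.date,
    config: RollupConfig = RollupConfig(),
) -> List[ClinicalNote]:
    """Filter one patient's notes by type and by distance to the index date."""
    return [
        n
        for n in notes
        if n.note_type in config.eligible_note_types
        and abs((n.note_date - index_date).days) <= config.window_days
    ]


def _tie_key(config: RollupConfig, index_date: _dt.date):
    after_loses = config.tie_break is TieBreak.PREFER_ON_OR_BEFORE

    def key(item):
        snippet, label_start = item
        delta = (snippet.note_date - index_date).days
        is_after = delta > 0
        return (
            abs(delta),
            is_after if after_loses else not is_after,
            snippet.note_id,
            label_start,
            snippet.snippet_id,
        )

    return key


def rollup_patient_stage(
    predictions: Sequence[Tuple[Snippet, SnippetPrediction]],
    index_date: _dt.date,
    config: RollupConfig = RollupConfig(),
    patient_id: Optional[str] = None,
) -> PatientStageRecord:
    """Assign stage per system from the closest-to-index labeled snippet.

    ``predictions`` pairs each snippet (carrying note id/date) with its
    extracted labels and must derive only from notes that passed
    :func:`select_notes` for this index date.
    """
    for snippet, _ in predictions:
        if abs((snippet.note_date - index_date).days) > config.window_days:
            raise ValueError(
                f"snippet {snippet.snippet_id} from note outside the "
                f"±{config.window_days}-day window"
            )
        if patient_id is None:
            patient_id = snippet.patient_id

    assignments: Dict[StagingSystem, StageAssignment] = {}
    for system in StagingSystem:
        # candidates: (snippet, label-provenance start within the note) per
        # label of this system; the provenance offset settles within-note ties
        candidates = []
        for snippet, pred in predictions:
            for label in sorted(pred.labels):
                if label.system is system:
                    span = pred.provenance.get(label)
                    start_in_note = (
                        snippet.window_start + span[0] if span else snippet.window_start
                    )
                    candidates.append(((snippet, start_in_note), label.value))
        if not candidates:
            continue
        key = _tie_key(config, index_date)
        (snippet, _), value = min(candidates, key=lambda c: (key(c[0]), c[1]))
        assignments[system] = StageAssignment(
            system=system,
            value=value,
            source_note_id=snippet.note_id,
            source_note_date=snippet.note_date,
            day_distance=abs((snippet.note_date - index_date).days),
        )
    return PatientStageRecord(patient_id or "", index_date, assignments)


def rollup_corpus(
    notes: Sequence[ClinicalNote],
    predictions: Mapping[str, SnippetPrediction],
    snippets: Sequence[Snippet],
    index_dates: Mapping[str, _dt.date],
    config: RollupConfig = RollupConfig(),
) -> List[PatientStageRecord]:
    """Roll up a whole corpus: filter notes per patient, then assign stage.

    ``predictions`` maps snippet_id to the extractor output; patients appear
    in ``index_dates`` order.  Patients with no eligible stage-bearing
    snippet yield a record with ``missing=True``.
    """
    notes_by_patient: Dict[str, List[ClinicalNote]] = {}
    for note in notes:
        notes_by_patient.setdefault(note.patient_id, []).append(note)
    snippets_by_note: Dict[str, List[Snippet]] = {}
    for snippet in snippets:
        snippets_by_note.setdefault(snippet.note_id, []).append(snippet)

    records = []
    for patient_id, index_date in index_dates.items():
        eligible = select_notes(notes_by_patient.get(patient_id, []), index_date, config)
        pairs = [
            (snippet, predictions[snippet.snippet_id])
            for note in eligible
            for snippet in snippets_by_note.get(note.note_id, [])
            if snippet.snippet_id in predictions
        ]
        records.append(
            rollup_patient_stage(pairs, index_date, config, patient_id=patient_id)
        )
    return records


def apply_system_preference(
    record: PatientStageRecord, order: Sequence[StagingSystem]
) -> Optional[StageAssignment]:
    """Optional post-processing: pick one assignment by a system hierarchy.

    Downstream analyses sometimes want a single stage per patient, preferring
    e.g. R-ISS over ISS over DS.  Returns the first available assignment in
    ``order``, or None if none of the listed systems was assigned.
    """
    for system in order:
        assignment = record.assignments.get(StagingSystem(system))
        if assignment is not None:
            return assignment
    return None
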