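"""Core domain types shared across the package.

The unit of extraction is a :class:`StageLabel` — a (staging system, stage
value) pair.  Multiple myeloma stage has been documented under three named
systems (R-ISS, ISS, Durie-Salmon), each with stages I-III; a stage value
written without naming its system is recorded under ``UNCLEAR``.  Durie-Salmon
subclasses A/B are collapsed into the bare stage value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Mapping, Optional


class StagingSystem(str, Enum):
    """The staging-system categories a stage value can be attributed to."""

    RISS = "RISS"
    ISS = "ISS"
    DS = "DS"
    UNCLEAR = "UNCLEAR"

    def __str__(self) -> str:  # keeps JSONL output readable
        return self.value


class NoteType(str, Enum):
    """Controlled note-type vocabulary used by the patient-level filters."""

    HEM_ONC = "HEM_ONC"
    PATHOLOGY = "PATHOLOGY"
    OTHER = "OTHER"

    def __str__(self) -> str:
        return self.value


VALID_STAGE_VALUES = (1, 2, 3)


@dataclass(frozen=True, order=True)
class StageLabel:
    """One extracted stage assertion: system plus integer stage value."""

    system: StagingSystem
    value: int

    def __post_init__(self) -> None:
        if self.value not in VALID_STAGE_VALUES:
            raise ValueError(f"stage value must be 1, 2 or 3, got {self.value!r}")
        if not isinstance(self.system, StagingSystem):
            object.__setattr__(self, "system", StagingSystem(self.system))


def check_label_set(labels: FrozenSet[StageLabel]) -> FrozenSet[StageLabel]:
    """Enforce the clear-over-unclear rule on a label set.

    A snippet annotated (or predicted) with any named-system label carries no
    UNCLEAR label: an unclear mention is only recorded when nothing clearer is
    present.
    """
    labels = frozenset(labels)
    has_clear = any(l.system is not StagingSystem.UNCLEAR for l in labels)
    has_unclear = any(l.system is StagingSystem.UNCLEAR for l in labels)
    if has_clear and has_unclear:
        raise ValueError(
            "label set mixes UNCLEAR with a named staging system: "
            f"{sorted(labels)}"
        )
    return labels


@dataclass(frozen=True)
class ClinicalNote:
    """One dated, typed free-text clinical document attached to a patient."""

    note_id: str
    patient_id: str
    note_date: _dt.date
    note_type: NoteType
    text: str


@dataclass(frozen=True)
class SnippetAnnotation:
    """Gold labels for one snippet; an empty set means "not stage"."""

    snippet_id: str
    labels: FrozenSet[StageLabel] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", check_label_set(self.labels))

    @property
    def is_stage(self) -> bool:
        return bool(self.labels)


@dataclass(frozen=True)
class PatientAnnotation:
    """Gold per-system stage for one patient at an index date.

    ``per_system`` is a partial mapping; a patient whose notes never document
    stage has an empty mapping and ``missing`` is true.
    """

    patient_id: str
    index_date: _dt.date
    per_system: Mapping[StagingSystem, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for sys_, val in dict(self.per_system).items():
            sys_ = StagingSystem(sys_)
            if val not in VALID_STAGE_VALUES:
                raise ValueError(f"stage value must be 1, 2 or 3, got {val!r}")
            clean[sys_] = int(val)
        object.__setattr__(self, "per_system", clean)

    @property
    def missing(self) -> bool:
        return not self.per_system


@dataclass(frozen=True)
class SnippetPrediction:
    """Extractor output for one snippet.

    ``provenance`` maps each label to the (value-span start, value-span end)
    character offsets within the snippet text that produced it.
    """

    snippet_id: str
    labels: FrozenSet[StageLabel] = frozenset()
    provenance: Mapping[StageLabel, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", check_label_set(self.labels))
        object.__setattr__(self, "provenance", dict(self.provenance))


def parse_date(raw: str) -> _dt.date:
    """Parse an ISO-8601 ``YYYY-MM-DD`` date string."""
    return _dt.date.fromisoformat(str(raw).strip())
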