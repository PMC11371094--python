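"""Readers and writers for the corpus, annotation and prediction formats.

The canonical on-disk format is JSONL, one object per line; clinical notes may
also be read from CSV.  Free text with embedded newlines survives JSON
untouched, which is why JSONL is canonical.  Dates are ISO-8601 days
(``YYYY-MM-DD``): all temporal logic in the package operates at day
granularity.

Schemas (all JSONL):

* ``notes.jsonl`` — ``{note_id, patient_id, note_date, note_type, text}``
* ``snippet_gold.jsonl`` — ``{snippet_id, labels: [{system, value}]}``;
  an empty ``labels`` list encodes "not stage"
* ``patient_gold.jsonl`` — ``{patient_id, index_date, per_system, missing}``
* ``predictions.jsonl`` — the snippet-gold shape plus a ``provenance`` field
  mapping ``"SYSTEM:value"`` to ``[start, end]`` span offsets

Readers raise :class:`CorpusFormatError` naming the offending line; no record
is ever silently dropped.  This module contains no domain logic.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Union

from .models import (
    ClinicalNote,
    NoteType,
    PatientAnnotation,
    SnippetAnnotation,
    SnippetPrediction,
    StageLabel,
    StagingSystem,
    parse_date,
)

logger = logging.getLogger(__name__)

_NOTE_FIELDS = ("note_id", "patient_id", "note_date", "note_type", "text")


class CorpusFormatError(ValueError):
    """A malformed record; carries the file path and 1-based line number."""

    def __init__(self, path: Union[str, Path], line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _iter_jsonl(path: Path):
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                yield line_no, json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(path, line_no, f"invalid JSON: {exc}") from exc


def _note_from_record(
    rec: Mapping, path: Path, line_no: int, note_type_map: Optional[Mapping[str, str]]
) -> ClinicalNote:
    for field_name in _NOTE_FIELDS:
        if field_name not in rec or rec[field_name] is None:
            raise CorpusFormatError(path, line_no, f"missing required field {field_name!r}")
    try:
        note_date = parse_date(rec["note_date"])
    except ValueError as exc:
        raise CorpusFormatError(
            path, line_no, f"unparseable note_date {rec['note_date']!r}"
        ) from exc
    raw_type = str(rec["note_type"])
    mapped = (note_type_map or {}).get(raw_type, raw_type)
    try:
        note_type = NoteType(mapped)
    except ValueError:
        logger.warning(
            "%s:%d: unknown note_type %r mapped to OTHER", path, line_no, raw_type
        )
        note_type = NoteType.OTHER
    return ClinicalNote(
        note_id=str(rec["note_id"]),
        patient_id=str(rec["patient_id"]),
        note_date=note_date,
        note_type=note_type,
        text=str(rec["text"]),
    )


def read_notes(
    path: Union[str, Path],
    note_type_map: Optional[Mapping[str, str]] = None,
) -> List[ClinicalNote]:
    """Read clinical notes from JSONL (default) or CSV, in file order.

    ``note_type_map`` translates raw note-title strings into the controlled
    vocabulary ``{HEM_ONC, PATHOLOGY, OTHER}``; raw values outside the
    vocabulary (after mapping) fall back to OTHER with a logged warning.
    """
    path = Path(path)
    notes: List[ClinicalNote] = []
    if path.suffix.lower() == ".csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, rec in enumerate(reader, start=2):  # header is line 1
                notes.append(_note_from_record(rec, path, line_no, note_type_map))
    else:
        for line_no, rec in _iter_jsonl(path):
            notes.append(_note_from_record(rec, path, line_no, note_type_map))
    return notes


def _labels_from_record(raw_labels, path: Path, line_no: int):
    labels = set()
    for item in raw_labels:
        try:
            system = StagingSystem(str(item["system"]).upper())
        except (ValueError, KeyError, TypeError) as exc:
            raise CorpusFormatError(path, line_no, f"unknown staging system in {item!r}") from exc
        try:
            value = int(item["value"])
            label = StageLabel(system, value)
        except (ValueError, KeyError, TypeError) as exc:
            raise CorpusFormatError(path, line_no, f"invalid stage value in {item!r}") from exc
        labels.add(label)
    return frozenset(labels)


def read_snippet_annotations(path: Union[str, Path]) -> List[SnippetAnnotation]:
    """Read snippet-level gold; an empty ``labels`` list means "not stage"."""
    path = Path(path)
    out = []
    for line_no, rec in _iter_jsonl(path):
        if "snippet_id" not in rec:
            raise CorpusFormatError(path, line_no, "missing required field 'snippet_id'")
        labels = _labels_from_record(rec.get("labels", []), path, line_no)
        try:
            out.append(SnippetAnnotation(str(rec["snippet_id"]), labels))
        except ValueError as exc:
            raise CorpusFormatError(path, line_no, str(exc)) from exc
    return out


def read_patient_annotations(path: Union[str, Path]) -> List[PatientAnnotation]:
    """Read patient-level gold; empty ``per_system`` means stage is missing."""
    path = Path(path)
    out = []
    for line_no, rec in _iter_jsonl(path):
        for field_name in ("patient_id", "index_date"):
            if field_name not in rec:
                raise CorpusFormatError(path, line_no, f"missing required field {field_name!r}")
        try:
            index_date = parse_date(rec["index_date"])
        except ValueError as exc:
            raise CorpusFormatError(
                path, line_no, f"unparseable index_date {rec['index_date']!r}"
            ) from exc
        per_system: Dict[StagingSystem, int] = {}
        for sys_str, val in (rec.get("per_system") or {}).items():
            try:
                per_system[StagingSystem(str(sys_str).upper())] = int(val)
            except ValueError as exc:
                raise CorpusFormatError(
                    path, line_no, f"unknown system or value {sys_str!r}: {val!r}"
                ) from exc
        ann = PatientAnnotation(str(rec["patient_id"]), index_date, per_system)
        if "missing" in rec and bool(rec["missing"]) != ann.missing:
            raise CorpusFormatError(
                path, line_no, "'missing' flag inconsistent with per_system contents"
            )
        out.append(ann)
    return out


def read_annotations(
    path: Union[str, Path], level: str
) -> Union[List[SnippetAnnotation], List[PatientAnnotation]]:
    """Dispatch on annotation ``level`` ("snippet" or "patient")."""
    if level == "snippet":
        return read_snippet_annotations(path)
    if level == "patient":
        return read_patient_annotations(path)
    raise ValueError(f"level must be 'snippet' or 'patient', got {level!r}")


def read_predictions(path: Union[str, Path]) -> List[SnippetPrediction]:
    """Read snippet predictions (gold shape plus provenance spans)."""
    path = Path(path)
    out = []
    for line_no, rec in _iter_jsonl(path):
        labels = _labels_from_record(rec.get("labels", []), path, line_no)
        provenance = {}
        for key, span in (rec.get("provenance") or {}).items():
            sys_str, _, val_str = key.partition(":")
            provenance[StageLabel(StagingSystem(sys_str), int(val_str))] = tuple(span)
        out.append(SnippetPrediction(str(rec["snippet_id"]), labels, provenance))
    return out


# ---------------------------------------------------------------------------
# serialization


def _label_to_obj(label: StageLabel) -> dict:
    return {"system": label.system.value, "value": label.value}


def record_to_obj(record) -> dict:
    """Convert any of the module's record types to a JSON-serializable dict."""
    if isinstance(record, ClinicalNote):
        return {
            "note_id": record.note_id,
            "patient_id": record.patient_id,
            "note_date": record.note_date.isoformat(),
            "note_type": record.note_type.value,
            "text": record.text,
        }
    if isinstance(record, SnippetAnnotation):
        return {
            "snippet_id": record.snippet_id,
            "labels": [_label_to_obj(l) for l in sorted(record.labels)],
        }
    if isinstance(record, PatientAnnotation):
        return {
            "patient_id": record.patient_id,
            "index_date": record.index_date.isoformat(),
            "per_system": {
                s.value: v for s, v in sorted(record.per_system.items())
            },
            "missing": record.missing,
        }
    if isinstance(record, SnippetPrediction):
        return {
            "snippet_id": record.snippet_id,
            "labels": [_label_to_obj(l) for l in sorted(record.labels)],
            "provenance": {
                f"{l.system.value}:{l.value}": list(span)
                for l, span in sorted(record.provenance.items())
            },
        }
    if hasattr(record, "to_obj"):
        return record.to_obj()
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_records(records: Iterable, path: Union[str, Path]) -> None:
    """Write records as JSONL; output is re-readable by the matching reader."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for record in records:
                fh.write(json.dumps(record_to_obj(record), ensure_ascii=False))
                fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write to {path}: {exc}") from exc
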