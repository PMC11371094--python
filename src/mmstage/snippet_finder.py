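"""Candidate stage-mention detection and snippet windowing.

A snippet is a fixed character window — by default 100 characters before and
200 after — cut around each match of a deliberately broad, case-insensitive
trigger pattern (the word "stage"/"staging", the system names ISS, R-ISS,
Durie-Salmon, and the abbreviations DS / D-S).  The trigger set over-generates
on purpose: downstream span rules are responsible for filtering, so recall is
what matters here.

Overlapping triggers (e.g. "ISS" inside "R-ISS") are resolved
leftmost-longest so each mention yields exactly one candidate.  Offsets are
0-based, half-open, counted in Unicode characters.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Union

from .corpus_io import _iter_jsonl
from .models import ClinicalNote, parse_date

#: Default trigger alternatives, ordered so that at any position the longest
#: possible alternative is listed first (this is what makes a plain
#: alternation behave leftmost-longest).
DEFAULT_TRIGGERS: tuple = (
    r"stag(?:ing|e[sd]?)",
    r"r-?iss",
    r"iss",
    r"durie[-\s/]?salmon",
    r"durie",
    r"d-?s",
)


@dataclass(frozen=True)
class SnippetWindowConfig:
    """Window sizes and trigger patterns for snippet construction."""

    chars_before: int = 100
    chars_after: int = 200
    candidate_pattern: Sequence[str] = DEFAULT_TRIGGERS

    def __post_init__(self) -> None:
        if self.chars_before < 0 or self.chars_after < 0:
            raise ValueError("window sizes must be non-negative")
        if not self.candidate_pattern:
            raise ValueError("candidate_pattern must be non-empty")

    def compiled(self) -> "re.Pattern[str]":
        body = "|".join(f"(?:{p})" for p in self.candidate_pattern)
        return re.compile(rf"\b(?:{body})\b", re.IGNORECASE)


@dataclass(frozen=True)
class CandidateMatch:
    """One trigger hit inside a note's text."""

    note_id: str
    start: int
    end: int
    matched_text: str


@dataclass(frozen=True)
class Snippet:
    """A character window around one candidate match, with note provenance."""

    snippet_id: str
    note_id: str
    patient_id: str
    note_date: _dt.date
    window_start: int
    window_end: int
    text: str
    trigger: CandidateMatch

    def to_obj(self) -> dict:
        return {
            "snippet_id": self.snippet_id,
            "note_id": self.note_id,
            "patient_id": self.patient_id,
            "note_date": self.note_date.isoformat(),
            "window_start": self.window_start,
            "window_end": self.window_end,
            "text": self.text,
            "trigger": {
                "start": self.trigger.start,
                "end": self.trigger.end,
                "matched_text": self.trigger.matched_text,
            },
        }

    @classmethod
    def from_obj(cls, rec: dict) -> "Snippet":
        trig = rec["trigger"]
        return cls(
            snippet_id=str(rec["snippet_id"]),
            note_id=str(rec["note_id"]),
            patient_id=str(rec["patient_id"]),
            note_date=parse_date(rec["note_date"]),
            window_start=int(rec["window_start"]),
            window_end=int(rec["window_end"]),
            text=str(rec["text"]),
            trigger=CandidateMatch(
                str(rec["note_id"]), int(trig["start"]), int(trig["end"]),
                str(trig["matched_text"]),
            ),
        )


def find_stage_candidates(
    text: str, config: SnippetWindowConfig = SnippetWindowConfig(), note_id: str = ""
) -> List[CandidateMatch]:
    """Scan note text for trigger matches, left to right, non-overlapping."""
    pattern = config.compiled()
    return [
        CandidateMatch(note_id, m.start(), m.end(), m.group(0))
        for m in pattern.finditer(text)
    ]


def make_snippet(
    note: ClinicalNote,
    match: CandidateMatch,
    config: SnippetWindowConfig = SnippetWindowConfig(),
) -> Snippet:
    """Cut the configured window around a match, clamped at note boundaries."""
    n = len(note.text)
    if not (0 <= match.start < match.end <= n):
        raise ValueError(
            f"match [{match.start},{match.end}) out of bounds for note of length {n}"
        )
    if note.text[match.start:match.end] != match.matched_text:
        raise ValueError("matched_text does not equal the note slice")
    window_start = max(0, match.start - config.chars_before)
    window_end = min(n, match.end + config.chars_after)
    return Snippet(
        snippet_id=f"{note.note_id}:{match.start}",
        note_id=note.note_id,
        patient_id=note.patient_id,
        note_date=note.note_date,
        window_start=window_start,
        window_end=window_end,
        text=note.text[window_start:window_end],
        trigger=match,
    )


def snippets_from_corpus(
    notes: Sequence[ClinicalNote],
    config: SnippetWindowConfig = SnippetWindowConfig(),
) -> List[Snippet]:
    """One snippet per candidate per note; note order, then offset order."""
    out: List[Snippet] = []
    for note in notes:
        for match in find_stage_candidates(note.text, config, note_id=note.note_id):
            out.append(make_snippet(note, match, config))
    return out


def read_snippets(path: Union[str, Path]) -> List[Snippet]:
    """Read a snippets.jsonl file produced by :func:`write_records`."""
    return [Snippet.from_obj(rec) for _, rec in _iter_jsonl(Path(path))]
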