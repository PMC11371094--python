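"""Seeded synthetic oncology-note corpus with ground-truth annotations.

Real staging corpora are restricted EHR data, so the package ships a
generator that emulates what matters to the extractor and the roll-up:
staging mentions in many surface forms ("R-ISS II", "ISS stage 3",
"Durie-Salmon IIIA", "stage II myeloma"), distractors that a naive pattern
would mislabel (chronic kidney disease stage, other-cancer stage, the
"Bactrim DS" double-strength antibiotic), and neutral filler prose, spread
over dated notes of mixed types around a per-patient index date.

Gold labels are computed from the template slots at generation time — never
by running the extractor — so extractor tests against this gold are not
circular.  Everything is driven by one ``random.Random(seed)``: the same
config yields byte-identical output files.

The generator does not attempt realistic clinical language: no section
headers, no lab tables, no negation, no abbreviations beyond the staging
vocabulary.  Passing tests on this corpus shows the rules behave as
specified on the covered surface forms, not that they cover all of real
clinical text.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

from . import corpus_io
from .models import (
    ClinicalNote,
    NoteType,
    PatientAnnotation,
    SnippetAnnotation,
    SnippetPrediction,
    StageLabel,
    StagingSystem,
)
from .patient_rollup import RollupConfig, TieBreak
from .snippet_finder import CandidateMatch, Snippet

_ROMAN = {1: "I", 2: "II", 3: "III"}

#: surface spellings per staging system, sampled uniformly
SYSTEM_SURFACES: Dict[StagingSystem, Tuple[str, ...]] = {
    StagingSystem.RISS: ("R-ISS", "RISS", "Revised ISS", "Revised International Staging System"),
    StagingSystem.ISS: ("ISS", "International Staging System"),
    StagingSystem.DS: ("Durie-Salmon", "Durie Salmon", "Durie/Salmon", "D-S"),
}

# neutral filler vocabulary; deliberately free of trigger tokens and of
# standalone roman-numeral lookalikes
_FILLER_WORDS = (
    "patient tolerated therapy well and reports no new complaints today "
    "review of systems otherwise negative continues current regimen "
    "without complication labs reviewed counts stable renal function at "
    "baseline will continue close monitoring follow up in clinic next "
    "month family present for visit questions answered plan unchanged "
    "performance status preserved appetite fair sleep adequate no fevers "
    "chills or night sweats neuropathy stable pain controlled"
).split()


def _filler(rng: random.Random, n_words: int = 14) -> str:
    words = [rng.choice(_FILLER_WORDS) for _ in range(n_words)]
    return " ".join(words).capitalize() + "."


@dataclass(frozen=True)
class TemplateCase:
    """A slotted sentence with gold labels derivable from its slots."""

    template_id: str
    text: str  # with {sys}, {val}, {val2}, {mm} slots
    category: str  # clear | unclear | multi | distractor | not_stage
    gold_systems: Tuple[Optional[StagingSystem], ...] = ()  # None → UNCLEAR


CLEAR_TEMPLATES = (
    "{mm} with {sys} stage {val} at diagnosis.",
    "Staging: {sys} {val}.",
    "{sys}: stage {val}, treatment options discussed.",
    "Found to have stage {val} by {sys} criteria.",
    "Assessment: {mm}, {sys} stage {val}.",
)

UNCLEAR_TEMPLATES = (
    "{mm}, stage {val} at diagnosis.",
    "Impression: stage {val} {mm}.",
    "Diagnosed with stage {val} disease last month.",
)

MULTI_TEMPLATES = (
    "Staging notable for {sys} {val} and {sys2} {val2}.",
)

RANGE_TEMPLATES = (
    "{mm} stage {val}-{val2} by {sys}.",
)

DISTRACTOR_TEMPLATES = (
    "CKD stage {val}, followed by nephrology.",
    "History of breast cancer stage {val}, resected.",
    "Bactrim DS 800-160 mg twice daily for prophylaxis.",
    "Stage {val} lymphoma in remission since 2010.",
    "COPD, stage {val} by spirometry.",
    "Chronic kidney disease stage {val} on recent labs.",
    "Prostate carcinoma, stage {val}, on surveillance.",
)

NOT_STAGE_TEMPLATES = (
    "Staging work-up is pending; marrow biopsy scheduled.",
    "Will proceed to the next stage of therapy as planned.",
    "Disease staging was reviewed with the patient in detail.",
    "Repeat staging scans ordered for next visit.",
)

_MM_SURFACES = ("multiple myeloma", "myeloma", "Multiple myeloma")


def _value_surface(value: int, rng: random.Random, system: Optional[StagingSystem]) -> str:
    form = rng.choice(("roman", "arabic"))
    text = _ROMAN[value] if form == "roman" else str(value)
    if system is StagingSystem.DS and rng.random() < 0.4:
        text += rng.choice(("A", "B"))
    return text


def render_template(
    template: str,
    system: Optional[StagingSystem],
    value: int,
    rng: random.Random,
    system2: Optional[StagingSystem] = None,
    value2: Optional[int] = None,
) -> Tuple[str, FrozenSet[StageLabel]]:
    """Fill a template's slots; gold is computed from the slots themselves."""
    slots = {
        "mm": rng.choice(_MM_SURFACES),
        "val": _value_surface(value, rng, system),
    }
    gold = set()
    if "{sys}" in template:
        assert system is not None
        slots["sys"] = rng.choice(SYSTEM_SURFACES[system])
    if "{sys2}" in template:
        assert system2 is not None
        slots["sys2"] = rng.choice(SYSTEM_SURFACES[system2])
    if "{val2}" in template:
        assert value2 is not None
        slots["val2"] = _value_surface(value2, rng, system2 or system)
    text = template.format(**slots)

    if template in DISTRACTOR_TEMPLATES or template in NOT_STAGE_TEMPLATES:
        return text, frozenset()
    primary = system if "{sys}" in template else StagingSystem.UNCLEAR
    gold.add(StageLabel(primary, value))
    if "{sys2}" in template:
        gold.add(StageLabel(system2, value2))
    elif "{val2}" in template:  # range: both endpoint values, same system
        gold.add(StageLabel(primary, value2))
    return text, frozenset(gold)


@dataclass(frozen=True)
class FixtureCase:
    """One rendered snippet-sized text with hand-derivable gold labels."""

    case_id: str
    text: str
    gold: FrozenSet[StageLabel]
    category: str


def template_suite(seed: int = 20240101) -> List[FixtureCase]:
    """The bundled fixture suite: every system x value x surface-form family,
    plus multi-label, range, unclear, distractor and not-stage cases.

    Deterministic for a given seed; used by the extractor's exact-match
    oracle tests.  Padding filler on both sides makes each case snippet-like.
    """
    rng = random.Random(seed)
    cases: List[FixtureCase] = []

    def add(text: str, gold, category: str) -> None:
        padded = f"{_filler(rng, 8)} {text} {_filler(rng, 8)}"
        cases.append(FixtureCase(f"tpl{len(cases):03d}", padded, frozenset(gold), category))

    for system in (StagingSystem.RISS, StagingSystem.ISS, StagingSystem.DS):
        for value in (1, 2, 3):
            for template in CLEAR_TEMPLATES[:3]:
                text, gold = render_template(template, system, value, rng)
                add(text, gold, "clear")
    for value in (1, 2, 3):
        for template in UNCLEAR_TEMPLATES:
            text, gold = render_template(template, None, value, rng)
            add(text, gold, "unclear")
    for system in (StagingSystem.RISS, StagingSystem.ISS, StagingSystem.DS):
        for template, value in zip(CLEAR_TEMPLATES[3:], (1, 3)):
            text, gold = render_template(template, system, value, rng)
            add(text, gold, "clear")
    for sys1, sys2 in (
        (StagingSystem.RISS, StagingSystem.ISS),
        (StagingSystem.ISS, StagingSystem.DS),
        (StagingSystem.RISS, StagingSystem.DS),
    ):
        text, gold = render_template(MULTI_TEMPLATES[0], sys1, 2, rng, system2=sys2, value2=3)
        add(text, gold, "multi")
    for system in (StagingSystem.ISS, StagingSystem.DS):
        text, gold = render_template(RANGE_TEMPLATES[0], system, 2, rng, value2=3)
        add(text, gold, "multi")
    for template in DISTRACTOR_TEMPLATES:
        text, gold = render_template(template, None, rng.choice((1, 2, 3)), rng)
        add(text, gold, "distractor")
    for template in NOT_STAGE_TEMPLATES:
        add(template, frozenset(), "not_stage")
    # hard cases: distractor and true mention in one window, hand-set gold
    add(
        "CKD stage 2 followed by nephrology as an outpatient in the community. "
        "Multiple myeloma with ISS stage III today.",
        {StageLabel(StagingSystem.ISS, 3)},
        "hard",
    )
    add(
        "Bactrim DS twice daily continues for prophylaxis without any issues. "
        "Myeloma staging: R-ISS 2.",
        {StageLabel(StagingSystem.RISS, 2)},
        "hard",
    )
    return cases


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    Defaults mirror a treated-myeloma note stream: a couple of notes per
    patient-year around treatment initiation, staging documented in roughly
    : 60% of stage-trigger contexts, all four label systems in circulation
    with named systems dominating, and distractor staging vocabulary (CKD,
    other cancers, antibiotic DS) in about a third of notes.
    """

    seed: int = 0
    n_patients: int = 200
    notes_per_patient: Tuple[int, int] = (2, 8)
    p_stage_mention: float = 0.6
    system_mix: Mapping[StagingSystem, float] = field(
        default_factory=lambda: {
            StagingSystem.RISS: 0.25,
            StagingSystem.ISS: 0.30,
            StagingSystem.DS: 0.20,
            StagingSystem.UNCLEAR: 0.25,
        }
    )
    value_mix: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.35, 3: 0.35}
    )
    p_distractor: float = 0.3
    p_multi_label: float = 0.1
    index_window_days: int = 540
    note_type_mix: Mapping[NoteType, float] = field(
        default_factory=lambda: {
            NoteType.HEM_ONC: 0.60,
            NoteType.PATHOLOGY: 0.15,
            NoteType.OTHER: 0.25,
        }
    )

    def __post_init__(self) -> None:
        for dist in (self.system_mix, self.value_mix, self.note_type_mix):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"distribution must sum to 1, got {total}")
        for p in (self.p_stage_mention, self.p_distractor, self.p_multi_label):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")


@dataclass(frozen=True)
class GoldMention:
    """One generated staging sentence with its gold labels and location."""

    snippet_id: str
    note_id: str
    patient_id: str
    note_date: _dt.date
    note_type: NoteType
    char_start: int
    char_end: int
    labels: FrozenSet[StageLabel]

    def to_obj(self) -> dict:
        return {
            "snippet_id": self.snippet_id,
            "labels": [
                {"system": l.system.value, "value": l.value} for l in sorted(self.labels)
            ],
            "note_id": self.note_id,
            "patient_id": self.patient_id,
            "note_date": self.note_date.isoformat(),
            "note_type": self.note_type.value,
            "char_start": self.char_start,
            "char_end": self.char_end,
        }


def _weighted_choice(rng: random.Random, dist: Mapping) -> object:
    keys = list(dist)
    return rng.choices(keys, weights=[dist[k] for k in keys], k=1)[0]


def generate_patient_history(
    config: GeneratorConfig,
    rng: random.Random,
    patient_id: str = "P0",
) -> Tuple[List[ClinicalNote], List[GoldMention], PatientAnnotation]:
    """One patient's dated notes plus internally consistent two-level gold.

    Patient-level gold is derived from the generated mentions by the same
    closest-note-per-system rule the roll-up implements (restricted to
    hematology/oncology and pathology notes within ±365 days), so rolling up
    the snippet gold reproduces the patient gold by construction.
    """
    index_date = _dt.date(2005, 1, 1) + _dt.timedelta(days=rng.randrange(0, 365 * 13))
    n_notes = rng.randint(*config.notes_per_patient)
    notes: List[ClinicalNote] = []
    mentions: List[GoldMention] = []

    for k in range(n_notes):
        note_id = f"{patient_id}-N{k:03d}"
        offset = rng.randint(-config.index_window_days, config.index_window_days)
        note_date = index_date + _dt.timedelta(days=offset)
        note_type = _weighted_choice(rng, config.note_type_mix)
        parts = [_filler(rng)]
        mention_slot: Optional[Tuple[int, str, FrozenSet[StageLabel]]] = None

        if rng.random() < config.p_stage_mention:
            system = _weighted_choice(rng, config.system_mix)
            value = _weighted_choice(rng, config.value_mix)
            if system is StagingSystem.UNCLEAR:
                template = rng.choice(UNCLEAR_TEMPLATES)
                text, gold = render_template(template, None, value, rng)
            elif rng.random() < config.p_multi_label:
                others = [
                    s
                    for s in (StagingSystem.RISS, StagingSystem.ISS, StagingSystem.DS)
                    if s is not system
                ]
                system2 = rng.choice(others)
                value2 = _weighted_choice(rng, config.value_mix)
                text, gold = render_template(
                    MULTI_TEMPLATES[0], system, value, rng, system2=system2, value2=value2
                )
            else:
                template = rng.choice(CLEAR_TEMPLATES)
                text, gold = render_template(template, system, value, rng)
            mention_slot = (len(parts), text, gold)
            parts.append(text)
            parts.append(_filler(rng))

        if rng.random() < config.p_distractor:
            template = rng.choice(DISTRACTOR_TEMPLATES)
            text, _ = render_template(template, None, rng.choice((1, 2, 3)), rng)
            parts.append(text)
            parts.append(_filler(rng))

        note_text = "\n".join(parts)
        notes.append(ClinicalNote(note_id, patient_id, note_date, note_type, note_text))
        if mention_slot is not None:
            slot_index, sent, gold = mention_slot
            start = sum(len(p) + 1 for p in parts[:slot_index])
            mentions.append(
                GoldMention(
                    snippet_id=f"{note_id}:m0",
                    note_id=note_id,
                    patient_id=patient_id,
                    note_date=note_date,
                    note_type=note_type,
                    char_start=start,
                    char_end=start + len(sent),
                    labels=gold,
                )
            )

    patient_gold = _patient_gold_from_mentions(patient_id, index_date, mentions)
    return notes, mentions, patient_gold


def _patient_gold_from_mentions(
    patient_id: str,
    index_date: _dt.date,
    mentions: Sequence[GoldMention],
    config: RollupConfig = RollupConfig(),
) -> PatientAnnotation:
    """Closest-mention-per-system gold, mirroring the documented roll-up rules."""
    per_system: Dict[StagingSystem, int] = {}
    for system in StagingSystem:
        candidates = []
        for m in mentions:
            if m.note_type not in config.eligible_note_types:
                continue
            delta = (m.note_date - index_date).days
            if abs(delta) > config.window_days:
                continue
            for label in sorted(m.labels):
                if label.system is system:
                    candidates.append(((abs(delta), delta > 0, m.note_id), label.value))
        if candidates:
            per_system[system] = min(candidates)[1]
    return PatientAnnotation(patient_id, index_date, per_system)


def mentions_to_rollup_inputs(
    mentions: Sequence[GoldMention],
) -> List[Tuple[Snippet, SnippetPrediction]]:
    """Adapt gold mentions to the (snippet, prediction) pairs roll-up expects."""
    pairs = []
    for m in mentions:
        trigger = CandidateMatch(m.note_id, m.char_start, m.char_start + 1, "")
        snippet = Snippet(
            snippet_id=m.snippet_id,
            note_id=m.note_id,
            patient_id=m.patient_id,
            note_date=m.note_date,
            window_start=m.char_start,
            window_end=m.char_end,
            text="",
            trigger=trigger,
        )
        pairs.append((snippet, SnippetPrediction(m.snippet_id, m.labels)))
    return pairs


@dataclass(frozen=True)
class SyntheticCorpus:
    notes: List[ClinicalNote]
    mentions: List[GoldMention]
    patient_gold: List[PatientAnnotation]

    @property
    def index_dates(self) -> Dict[str, _dt.date]:
        return {p.patient_id: p.index_date for p in self.patient_gold}


def generate_corpus_data(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate the full corpus in memory; deterministic in ``config.seed``."""
    rng = random.Random(config.seed)
    notes, mentions, patient_gold = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        p_notes, p_mentions, p_gold = generate_patient_history(config, rng, patient_id=pid)
        notes.extend(p_notes)
        mentions.extend(p_mentions)
        patient_gold.append(p_gold)
    return SyntheticCorpus(notes, mentions, patient_gold)


def generate_corpus(config: GeneratorConfig, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write notes, snippet gold, patient gold and index dates to ``out_dir``.

    Same config -> byte-identical files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = generate_corpus_data(config)
    paths = {
        "notes": out_dir / "notes.jsonl",
        "snippet_gold": out_dir / "snippet_gold.jsonl",
        "patient_gold": out_dir / "patient_gold.jsonl",
        "index_dates": out_dir / "index_dates.jsonl",
    }
    corpus_io.write_records(corpus.notes, paths["notes"])
    corpus_io.write_records(corpus.mentions, paths["snippet_gold"])
    corpus_io.write_records(corpus.patient_gold, paths["patient_gold"])

    @dataclass(frozen=True)
    class _IndexRow:
        patient_id: str
        index_date: _dt.date

        def to_obj(self) -> dict:
            return {"patient_id": self.patient_id, "index_date": self.index_date.isoformat()}

    corpus_io.write_records(
        [_IndexRow(p, d) for p, d in corpus.index_dates.items()], paths["index_dates"]
    )
    return paths
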