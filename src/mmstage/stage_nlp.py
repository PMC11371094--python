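"""Snippet-level stage extraction: the core rule pipeline.

The extractor is a pipeline of ordered regular-expression rules applied to a
snippet's text:

1. **Span labeling** (:func:`label_spans`) — mark stage values (``3``,
   ``III``, ``II-III``, ``IIIA``), staging-system names (ISS, R-ISS,
   Durie-Salmon and their spelled-out variants), mentions of multiple
   myeloma, mentions of *other* staged diseases (chronic kidney disease,
   non-myeloma cancers), and antibiotic names whose "DS" (double strength)
   suffix shadows the Durie-Salmon abbreviation.
2. **Overlap resolution** (:func:`resolve_overlaps`) — among same-category
   spans that overlap, the span from the earliest rule wins.
3. **Context suppression** (:func:`suppress_nonmm_context`) — stage values
   near another-disease mention are discarded (a "CKD stage 3" is not a
   myeloma stage), and DS system spans near an antibiotic are discarded
   ("Bactrim DS" is a drug strength, not a staging system).
4. **Association** (:func:`associate_stage_labels`) — each surviving stage
   value is linked to the nearest staging system within a character window,
   preferring directly-connected and preceding systems; a value with no
   system in range becomes an UNCLEAR-system label.  If any named-system
   label is present, UNCLEAR labels are dropped, mirroring the annotation
   convention that only clearly documented systems are recorded when both
   occur.

A stage value is only recognized in an anchoring context — after the word
"stage"/"staging" or adjacent to a staging-system name — so stray numerals
and roman-numeral lookalikes in prose never become labels.  All lexicons and
windows live in :class:`RuleSet`, which round-trips through YAML so rules can
be iterated on without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

import yaml

from .models import SnippetPrediction, StageLabel, StagingSystem, check_label_set
from .snippet_finder import Snippet

__all__ = [
    "StagingSystem", "StageLabel", "SpanCategory", "Span", "RuleSet",
    "default_ruleset", "normalize_stage_value", "normalize_system_name",
    "label_spans", "resolve_overlaps", "suppress_nonmm_context",
    "associate_stage_labels", "extract_snippet_stage",
]


class SpanCategory(str, Enum):
    STAGE_VALUE = "STAGE_VALUE"
    STAGING_SYSTEM = "STAGING_SYSTEM"
    OTHER_DISEASE = "OTHER_DISEASE"
    MM_MENTION = "MM_MENTION"
    ANTIBIOTIC = "ANTIBIOTIC"


@dataclass(frozen=True)
class Span:
    """A labeled character interval within a snippet's text.

    ``normalized`` depends on the category: a tuple of integer stage values
    for STAGE_VALUE (length > 1 for ranges like "II-III"), a
    :class:`StagingSystem` for STAGING_SYSTEM, and a lower-cased term id
    otherwise.  ``rule_priority`` is the index of the producing rule in the
    total rule order; lower wins on same-category overlap.
    """

    category: SpanCategory
    start: int
    end: int
    raw: str
    normalized: object
    rule_priority: int


# --- building blocks for the default rules ---------------------------------

_RISS_RE = r"(?:revised\s+(?:international\s+staging\s+system|iss)|r-?iss)"
_ISS_RE = r"(?:international\s+staging\s+system|iss)"
_DS_RE = r"(?:durie[-\s/]?salmon|d-?s)"
_ANY_SYS = rf"(?:{_RISS_RE}|{_ISS_RE}|{_DS_RE})"

_VAL_ATOM = r"(?:i{1,3}|[123])(?:\s?[ab])?"
_VAL_RANGE = rf"{_VAL_ATOM}(?:\s*[-–—/]\s*{_VAL_ATOM})?"

_STAGE_KW = r"stag(?:e|ing)"

_DEFAULT_SYSTEM_RULES: Tuple[Tuple[str, str], ...] = (
    (rf"\b{_RISS_RE}\b", "RISS"),
    (rf"\b{_ISS_RE}\b", "ISS"),
    (rf"\b{_DS_RE}\b", "DS"),
)

_DEFAULT_VALUE_RULES: Tuple[str, ...] = (
    # after the stage keyword: "stage III", "staging: 2", "stage is II-III"
    rf"\b{_STAGE_KW}\s*(?:is|was|of|:|=|-)?\s*(?P<val>{_VAL_RANGE})\b",
    # after a system name: "ISS 3", "R-ISS: II", "Durie-Salmon stage IIIA"
    rf"\b{_ANY_SYS}\b\s*[-:,]?\s*(?:{_STAGE_KW}\s*(?:is|was|:)?\s*)?(?P<val>{_VAL_RANGE})\b",
    # before a system name: "III by ISS", "2, per Durie-Salmon"
    rf"\b(?P<val>{_VAL_RANGE})\b\s*(?:,?\s*(?:by|per|according\s+to|on|via)\s+(?:the\s+)?)?(?=\b{_ANY_SYS}\b)",
)

_DEFAULT_MM = (r"\bmultiple\s+myeloma\b", r"\bmyeloma\b", r"\bplasma\s+cell\s+neoplasm\b", r"\bmm\b")

_DEFAULT_OTHER_DISEASE = (
    r"\bchronic\s+kidney\s+disease\b",
    r"\bckd\b",
    r"\bcancer\b",
    r"\bcarcinoma\b",
    r"\blymphoma\b",
    r"\bmelanoma\b",
    r"\bsarcoma\b",
    r"\bleukemia\b",
    r"\bheart\s+failure\b",
    r"\bnyha\b",
    r"\bcopd\b",
    r"\bfibrosis\b",
    r"\b(?:pressure|decubitus)\s+ulcers?\b",
)

_DEFAULT_ANTIBIOTIC = (
    r"\bbactrim\b",
    r"\bseptra\b",
    r"\btrimethoprim(?:[-/\s]sulfamethoxazole)?\b",
    r"\bsulfamethoxazole\b",
    r"\btmp[-/\s]?smx\b",
    r"\bco-?trimoxazole\b",
)

# text allowed between a stage value and the system it is read as belonging
# to: whitespace/punctuation and light connective words only
_DEFAULT_CONNECTIVE = (
    r"[\s:,\-–—()]*"
    r"(?:(?:by|per|according\s+to|on|via|is|was|of|the|a|an|stag(?:e|ing)|"
    r"score|currently|now|with)[\s:,\-–—()]*)*"
)


@dataclass(frozen=True)
class RuleSet:
    """All rules, lexicons and windows of the extractor, in evaluation order.

    Rule priority for overlap resolution is the position of a rule in the
    concatenation ``system_rules + value_rules + mm + other_disease +
    antibiotic``.  Proximity windows are character distances measured between
    the nearest edges of two spans.
    """

    system_rules: Tuple[Tuple[str, str], ...] = _DEFAULT_SYSTEM_RULES
    value_rules: Tuple[str, ...] = _DEFAULT_VALUE_RULES
    mm_patterns: Tuple[str, ...] = _DEFAULT_MM
    other_disease_patterns: Tuple[str, ...] = _DEFAULT_OTHER_DISEASE
    antibiotic_patterns: Tuple[str, ...] = _DEFAULT_ANTIBIOTIC
    suppression_window: int = 50
    association_window: int = 40
    connective_pattern: str = _DEFAULT_CONNECTIVE
    # a bare "DS"/"D-S" token is only accepted as a staging system when a
    # myeloma mention or a stage value sits within the association window
    ds_bare_guard: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "system_rules", tuple(map(tuple, self.system_rules)))
        object.__setattr__(self, "value_rules", tuple(self.value_rules))
        object.__setattr__(self, "mm_patterns", tuple(self.mm_patterns))
        object.__setattr__(self, "other_disease_patterns", tuple(self.other_disease_patterns))
        object.__setattr__(self, "antibiotic_patterns", tuple(self.antibiotic_patterns))

    # ordered (priority, category, compiled pattern, payload) tuples
    def compiled_rules(self):
        cache = getattr(self, "_compiled", None)
        if cache is not None:
            return cache
        rules = []
        prio = 0
        for pat, sys_name in self.system_rules:
            rules.append((prio, SpanCategory.STAGING_SYSTEM, re.compile(pat, re.I), StagingSystem(sys_name)))
            prio += 1
        for pat in self.value_rules:
            rules.append((prio, SpanCategory.STAGE_VALUE, re.compile(pat, re.I), None))
            prio += 1
        for category, pats in (
            (SpanCategory.MM_MENTION, self.mm_patterns),
            (SpanCategory.OTHER_DISEASE, self.other_disease_patterns),
            (SpanCategory.ANTIBIOTIC, self.antibiotic_patterns),
        ):
            for pat in pats:
                rules.append((prio, category, re.compile(pat, re.I), None))
                prio += 1
        object.__setattr__(self, "_compiled", tuple(rules))
        return self._compiled

    def to_yaml(self, path: Union[str, Path]) -> None:
        obj = {
            "system_rules": [list(r) for r in self.system_rules],
            "value_rules": list(self.value_rules),
            "mm_patterns": list(self.mm_patterns),
            "other_disease_patterns": list(self.other_disease_patterns),
            "antibiotic_patterns": list(self.antibiotic_patterns),
            "suppression_window": self.suppression_window,
            "association_window": self.association_window,
            "connective_pattern": self.connective_pattern,
            "ds_bare_guard": self.ds_bare_guard,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(obj, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            obj = yaml.safe_load(fh)
        obj["system_rules"] = tuple((p, s) for p, s in obj.get("system_rules", []))
        return cls(**obj)


def default_ruleset() -> RuleSet:
    """The shipped rule set, re-derived from the published rule description."""
    return RuleSet()


# --- normalization ----------------------------------------------------------

_ROMAN = {"i": 1, "ii": 2, "iii": 3}
_SINGLE_VALUE_RE = re.compile(r"(i{1,3}|[123])\s?[ab]?", re.I)


def normalize_stage_value(raw: str) -> Optional[int]:
    """Map one stage-value spelling to an integer stage, or None to reject.

    Roman numerals I/II/III (any case) and arabic 1/2/3 are accepted; a
    trailing Durie-Salmon subclass letter A/B is stripped first.  Anything
    else — IV, 4, 0 — is rejected (a value, not an exception).
    """
    m = _SINGLE_VALUE_RE.fullmatch(raw.strip())
    if not m:
        return None
    core = m.group(1).lower()
    return _ROMAN.get(core, None) if core in _ROMAN else int(core)


_RANGE_SPLIT_RE = re.compile(r"\s*[-–—/]\s*")


def _normalize_value_span(raw: str) -> Tuple[int, ...]:
    """Normalize a (possibly ranged) value span; ranges expand to both ends."""
    values = []
    for part in _RANGE_SPLIT_RE.split(raw.strip()):
        v = normalize_stage_value(part)
        if v is None:
            return ()
        values.append(v)
    return tuple(sorted(set(values)))


_SYSTEM_VARIANTS = (
    (re.compile(rf"{_RISS_RE}$", re.I), StagingSystem.RISS),
    (re.compile(rf"{_ISS_RE}$", re.I), StagingSystem.ISS),
    (re.compile(rf"(?:{_DS_RE}|durie)$", re.I), StagingSystem.DS),
)


def normalize_system_name(raw: str) -> StagingSystem:
    """Map a staging-system spelling variant to its canonical system."""
    cleaned = re.sub(r"\s+", " ", raw.strip())
    for pattern, system in _SYSTEM_VARIANTS:
        if pattern.fullmatch(cleaned):
            return system
    raise ValueError(f"unknown staging system name: {raw!r}")


# --- the four pipeline stages ----------------------------------------------


def label_spans(text: str, rules: RuleSet = None) -> List[Span]:
    """Run every rule over the text; overlaps are NOT yet resolved."""
    rules = rules or default_ruleset()
    spans: List[Span] = []
    for prio, category, pattern, payload in rules.compiled_rules():
        for m in pattern.finditer(text):
            if category is SpanCategory.STAGE_VALUE:
                start, end = m.span("val")
                normalized = _normalize_value_span(m.group("val"))
                if not normalized:
                    continue
            else:
                start, end = m.span()
                normalized = payload if payload is not None else m.group(0).lower()
            spans.append(Span(category, start, end, text[start:end], normalized, prio))
    spans.sort(key=lambda s: (s.start, s.end, s.rule_priority, s.category.value))
    return spans


def _overlap(a: Span, b: Span) -> bool:
    return a.start < b.end and b.start < a.end


def resolve_overlaps(spans: Sequence[Span]) -> List[Span]:
    """Keep, per category, the earliest-rule span among overlapping ones.

    Ties on rule priority go to the leftmost span, then the longest.
    Cross-category overlaps are all retained.
    """
    kept: List[Span] = []
    for span in sorted(spans, key=lambda s: (s.rule_priority, s.start, -(s.end - s.start))):
        if any(k.category is span.category and _overlap(k, span) for k in kept):
            continue
        kept.append(span)
    kept.sort(key=lambda s: (s.start, s.end, s.rule_priority))
    return kept


def _gap(a: Span, b: Span) -> int:
    """Character distance between the nearest edges of two spans (0 if overlapping)."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


_BARE_DS_RE = re.compile(r"d-?s", re.I)


def suppress_nonmm_context(spans: Sequence[Span], rules: RuleSet = None) -> List[Span]:
    """Discard stage values near other diseases and DS spans near antibiotics."""
    rules = rules or default_ruleset()
    spans = list(spans)
    diseases = [s for s in spans if s.category is SpanCategory.OTHER_DISEASE]
    antibiotics = [s for s in spans if s.category is SpanCategory.ANTIBIOTIC]

    def near(span, others, window):
        return any(_gap(span, o) <= window for o in others)

    out = []
    for span in spans:
        if span.category is SpanCategory.STAGE_VALUE and near(
            span, diseases, rules.suppression_window
        ):
            continue
        if (
            span.category is SpanCategory.STAGING_SYSTEM
            and span.normalized is StagingSystem.DS
            and near(span, antibiotics, rules.suppression_window)
        ):
            continue
        out.append(span)

    if rules.ds_bare_guard:
        values = [s for s in out if s.category is SpanCategory.STAGE_VALUE]
        mm = [s for s in out if s.category is SpanCategory.MM_MENTION]
        guarded = []
        for span in out:
            if (
                span.category is SpanCategory.STAGING_SYSTEM
                and span.normalized is StagingSystem.DS
                and _BARE_DS_RE.fullmatch(span.raw)
                and not near(span, values + mm, rules.association_window)
            ):
                continue
            guarded.append(span)
        out = guarded
    return out


def associate_stage_labels(
    spans: Sequence[Span],
    rules: RuleSet = None,
    text: Optional[str] = None,
) -> Tuple[FrozenSet[StageLabel], Dict[StageLabel, Tuple[int, int]]]:
    """Link stage values to systems; systemless values become UNCLEAR.

    Each surviving stage value takes the staging system within the
    association window that is (in order of preference) directly connected
    by connective material only, nearest by character gap, preceding the
    value, leftmost.  The final set is deduplicated; if any named-system
    label is present, UNCLEAR labels are removed.
    """
    rules = rules or default_ruleset()
    connective = re.compile(rules.connective_pattern, re.I)
    systems = [s for s in spans if s.category is SpanCategory.STAGING_SYSTEM]
    values = [s for s in spans if s.category is SpanCategory.STAGE_VALUE]

    def directly_connected(v: Span, s: Span) -> bool:
        if text is None:
            return False
        lo, hi = (v.end, s.start) if v.end <= s.start else (s.end, v.start)
        return connective.fullmatch(text[lo:hi]) is not None

    labels: Set[StageLabel] = set()
    provenance: Dict[StageLabel, Tuple[int, int]] = {}
    for v in sorted(values, key=lambda s: (s.start, s.end)):
        candidates = [s for s in systems if _gap(v, s) <= rules.association_window]
        if candidates:
            chosen = min(
                candidates,
                key=lambda s: (
                    not directly_connected(v, s),
                    _gap(v, s),
                    s.start > v.start,  # prefer a preceding system on ties
                    s.start,
                ),
            )
            system = chosen.normalized
        else:
            system = StagingSystem.UNCLEAR
        for value in v.normalized:
            label = StageLabel(system, value)
            labels.add(label)
            provenance.setdefault(label, (v.start, v.end))

    if any(l.system is not StagingSystem.UNCLEAR for l in labels):
        labels = {l for l in labels if l.system is not StagingSystem.UNCLEAR}
        provenance = {l: sp for l, sp in provenance.items() if l in labels}
    return check_label_set(frozenset(labels)), provenance


def extract_snippet_stage(snippet: Snippet, rules: RuleSet = None) -> SnippetPrediction:
    """Full pipeline on one snippet; an empty label set encodes "not stage"."""
    rules = rules or default_ruleset()
    spans = label_spans(snippet.text, rules)
    spans = resolve_overlaps(spans)
    spans = suppress_nonmm_context(spans, rules)
    labels, provenance = associate_stage_labels(spans, rules, text=snippet.text)
    return SnippetPrediction(snippet.snippet_id, labels, provenance)


def extract_text_stage(text: str, rules: RuleSet = None) -> FrozenSet[StageLabel]:
    """Convenience: run the pipeline on bare text, returning only labels."""
    rules = rules or default_ruleset()
    spans = suppress_nonmm_context(resolve_overlaps(label_spans(text, rules)), rules)
    labels, _ = associate_stage_labels(spans, rules, text=text)
    return labels
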