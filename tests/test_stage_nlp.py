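"""The snippet-level extractor: normalization, spans, suppression, association."""

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from mmstage.models import StageLabel, StagingSystem
from mmstage.snippet_finder import CandidateMatch, Snippet
from mmstage.stage_nlp import (
    RuleSet,
    Span,
    SpanCategory,
    associate_stage_labels,
    default_ruleset,
    extract_snippet_stage,
    extract_text_stage,
    label_spans,
    normalize_stage_value,
    normalize_system_name,
    resolve_overlaps,
    suppress_nonmm_context,
)
from mmstage.synthetic_corpus import template_suite


def lbl(system, value):
    return StageLabel(StagingSystem[system], value)


class TestNormalizeStageValue:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("III", 3), ("ii", 2), ("I", 1), ("2", 2),
            ("IIIA", 3), ("IIIB", 3), ("iiia", 3), ("3A", 3), ("1 B", 1),
            ("IV", None), ("4", None), ("0", None), ("", None),
            ("IIIC", None), ("stage", None), ("33", None),
        ],
    )
    def test_valid_forms_map_and_invalid_reject(self, raw, expected):
        assert normalize_stage_value(raw) == expected


class TestNormalizeSystemName:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("ISS", StagingSystem.ISS),
            ("International Staging System", StagingSystem.ISS),
            ("international  staging system", StagingSystem.ISS),
            ("R-ISS", StagingSystem.RISS),
            ("RISS", StagingSystem.RISS),
            ("Revised ISS", StagingSystem.RISS),
            ("Revised International Staging System", StagingSystem.RISS),
            ("DS", StagingSystem.DS),
            ("D-S", StagingSystem.DS),
            ("Durie-Salmon", StagingSystem.DS),
            ("Durie Salmon", StagingSystem.DS),
            ("Durie/Salmon", StagingSystem.DS),
        ],
    )
    def test_variants_map_to_canonical_system(self, raw, expected):
        assert normalize_system_name(raw) is expected

    def test_unknown_name_is_contract_error(self):
        with pytest.raises(ValueError, match="unknown staging system"):
            normalize_system_name("TNM")


class TestLabelSpans:
    def test_system_and_value_spans_with_offsets(self):
        spans = label_spans("ISS stage III")
        by_cat = {}
        for s in spans:
            by_cat.setdefault(s.category, []).append(s)
        assert any(
            s.raw == "ISS" and s.normalized is StagingSystem.ISS
            for s in by_cat[SpanCategory.STAGING_SYSTEM]
        )
        assert any(s.raw == "III" and s.normalized == (3,) for s in by_cat[SpanCategory.STAGE_VALUE])
        for s in spans:
            assert "ISS stage III"[s.start:s.end] == s.raw

    def test_other_disease_and_value_both_emitted(self):
        spans = label_spans("CKD stage 3")
        cats = {s.category for s in spans}
        assert SpanCategory.OTHER_DISEASE in cats
        assert SpanCategory.STAGE_VALUE in cats

    def test_empty_text_yields_no_spans(self):
        assert label_spans("") == []

    def test_range_value_normalizes_to_both_endpoints(self):
        spans = label_spans("stage II-III by Durie-Salmon")
        values = [s for s in spans if s.category is SpanCategory.STAGE_VALUE]
        assert any(s.normalized == (2, 3) for s in values)

    def test_antibiotic_and_mm_lexicons_fire(self):
        spans = label_spans("multiple myeloma on Bactrim")
        cats = {s.category for s in spans}
        assert SpanCategory.MM_MENTION in cats and SpanCategory.ANTIBIOTIC in cats


def _span(cat, start, end, prio, normalized=(3,)):
    return Span(SpanCategory[cat], start, end, "x" * (end - start), normalized, prio)


class TestResolveOverlaps:
    def test_same_span_from_two_rules_keeps_earliest_rule(self):
        a = _span("STAGE_VALUE", 10, 13, 2)
        b = _span("STAGE_VALUE", 10, 13, 5)
        assert resolve_overlaps([b, a]) == [a]

    def test_riss_span_beats_contained_iss_span(self):
        riss = _span("STAGING_SYSTEM", 0, 5, 0, StagingSystem.RISS)
        iss = _span("STAGING_SYSTEM", 2, 5, 1, StagingSystem.ISS)
        assert resolve_overlaps([iss, riss]) == [riss]

    def test_disjoint_spans_unchanged(self):
        spans = [_span("STAGE_VALUE", 0, 3, 1), _span("STAGE_VALUE", 5, 8, 2)]
        assert resolve_overlaps(spans) == spans

    def test_cross_category_overlaps_retained(self):
        sys_span = _span("STAGING_SYSTEM", 0, 5, 0, StagingSystem.DS)
        val_span = _span("STAGE_VALUE", 3, 6, 4)
        assert set(resolve_overlaps([sys_span, val_span])) == {sys_span, val_span}

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["STAGE_VALUE", "STAGING_SYSTEM", "OTHER_DISEASE"]),
                st.integers(0, 30),
                st.integers(1, 8),
                st.integers(0, 6),
            ).map(lambda t: _span(t[0], t[1], t[1] + t[2], t[3])),
            max_size=12,
        )
    )
    def test_survivor_set_is_the_greedy_fixed_point(self, spans):
        """Characterizing properties: survivors never overlap within a
        category, and every dropped span overlaps a surviving same-category
        span produced by an earlier rule (or equal rule, more leftward /
        longer)."""
        kept = resolve_overlaps(spans)
        kept_set = set(kept)

        def overlap(a, b):
            return a.start < b.end and b.start < a.end

        def key(s):
            return (s.rule_priority, s.start, -(s.end - s.start))

        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not (a.category is b.category and overlap(a, b) and a != b)
        for s in spans:
            if s in kept_set:
                continue
            assert any(
                k.category is s.category and overlap(k, s) and key(k) <= key(s)
                for k in kept
            )


class TestSuppression:
    def _spans(self, text):
        return resolve_overlaps(label_spans(text))

    def test_value_near_other_disease_discarded(self):
        out = suppress_nonmm_context(self._spans("CKD stage III"))
        assert not any(s.category is SpanCategory.STAGE_VALUE for s in out)

    def test_ds_system_near_antibiotic_discarded(self):
        out = suppress_nonmm_context(self._spans("Bactrim DS bid"))
        assert not any(s.category is SpanCategory.STAGING_SYSTEM for s in out)

    def test_clean_mention_untouched(self):
        spans = self._spans("ISS stage III")
        assert suppress_nonmm_context(spans) == spans

    def test_bare_ds_without_mm_or_value_support_dropped(self):
        out = suppress_nonmm_context(self._spans("DS reviewed the chart"))
        assert not any(s.category is SpanCategory.STAGING_SYSTEM for s in out)

    def test_bare_ds_with_stage_value_support_kept(self):
        out = suppress_nonmm_context(self._spans("DS stage II myeloma"))
        assert any(
            s.category is SpanCategory.STAGING_SYSTEM and s.normalized is StagingSystem.DS
            for s in out
        )

    def test_distant_disease_does_not_suppress(self):
        text = "CKD noted." + " filler" * 12 + " ISS stage III"
        out = suppress_nonmm_context(self._spans(text))
        assert any(s.category is SpanCategory.STAGE_VALUE for s in out)


class TestAssociation:
    def _labels(self, text):
        spans = suppress_nonmm_context(resolve_overlaps(label_spans(text)))
        labels, _ = associate_stage_labels(spans, text=text)
        return labels

    def test_each_value_links_to_nearest_system(self):
        assert self._labels("R-ISS 2 and ISS 3") == {lbl("RISS", 2), lbl("ISS", 3)}

    def test_systemless_value_becomes_unclear(self):
        assert self._labels("stage II myeloma") == {lbl("UNCLEAR", 2)}

    def test_clear_label_suppresses_unclear(self):
        assert self._labels("ISS stage III, previously noted as stage 3") == {lbl("ISS", 3)}

    def test_provenance_points_at_value_span(self):
        text = "ISS stage III"
        spans = suppress_nonmm_context(resolve_overlaps(label_spans(text)))
        labels, provenance = associate_stage_labels(spans, text=text)
        (start, end) = provenance[lbl("ISS", 3)]
        assert text[start:end] == "III"


def make_snip(text, snippet_id="s1"):
    return Snippet(snippet_id, "n1", "p1", dt.date(2015, 1, 1), 0, len(text), text,
                   CandidateMatch("n1", 0, 1, text[:1]))


EXTRACT_CASES = [
    ("...multiple myeloma, ISS stage III...", {lbl("ISS", 3)}),
    ("...Bactrim DS 800-160 bid...", set()),
    ("...stage II-III by Durie-Salmon...", {lbl("DS", 2), lbl("DS", 3)}),
    ("Durie-Salmon IIIA at presentation", {lbl("DS", 3)}),
    ("Revised International Staging System II", {lbl("RISS", 2)}),
    ("CKD stage 3, on lisinopril", set()),
    ("History of breast cancer stage II in 2005", set()),
    ("Staging work-up is pending", set()),
]


@pytest.mark.parametrize("text,expected", EXTRACT_CASES, ids=[c[0][:30] for c in EXTRACT_CASES])
def test_extract_pipeline_end_to_end(text, expected):
    pred = extract_snippet_stage(make_snip(text))
    assert pred.labels == frozenset(expected)
    assert set(pred.provenance) == pred.labels


def test_extraction_deterministic():
    snip = make_snip("myeloma R-ISS stage II and CKD stage 3")
    assert extract_snippet_stage(snip) == extract_snippet_stage(snip)


def test_every_label_in_valid_domain_on_fixture_suite():
    for case in template_suite():
        for label in extract_text_stage(case.text):
            assert label.value in (1, 2, 3)
            assert isinstance(label.system, StagingSystem)


def test_fixture_suite_predictions_match_stored_gold_exactly():
    mismatches = [
        case.case_id
        for case in template_suite()
        if extract_text_stage(case.text) != case.gold
    ]
    assert mismatches == []


def test_growing_disease_lexicon_never_adds_labels():
    base = default_ruleset()
    widened = RuleSet(
        other_disease_patterns=base.other_disease_patterns
        + (r"\bnephrology\b", r"\bremission\b", r"\bspirometry\b"),
    )
    for case in template_suite():
        assert extract_text_stage(case.text, widened) <= extract_text_stage(case.text, base)


def test_ruleset_yaml_round_trip_preserves_behavior(tmp_path):
    base = default_ruleset()
    path = tmp_path / "rules.yaml"
    base.to_yaml(path)
    loaded = RuleSet.from_yaml(path)
    for case in template_suite()[:10]:
        assert extract_text_stage(case.text, loaded) == extract_text_stage(case.text, base)
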