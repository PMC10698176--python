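"""FAIR checklist survey: validation, aggregation, response IO."""

import itertools
import random

import pytest
from pydantic import ValidationError

from cdomeval.survey import (
    Answer,
    BarrierRating,
    ChecklistItem,
    FAIRCategory,
    SurveyResponse,
    aggregate_barriers,
    aggregate_checklist,
    default_checklist,
    normalize_barrier_name,
    read_responses,
    validate_response,
    write_responses,
)

BARRIER_DEFAULTS = {
    "limited_financial": BarrierRating.NOT_IMPORTANT,
    "limited_human": BarrierRating.NOT_IMPORTANT,
    "limited_technical": BarrierRating.NOT_IMPORTANT,
    "limited_incentives": BarrierRating.NOT_IMPORTANT,
}


def response(rid="r1", answers=None, barriers=None, comments=None):
    return SurveyResponse(
        respondent_id=rid,
        answers=answers or {},
        comments=comments or {},
        barriers=BARRIER_DEFAULTS | (barriers or {}),
    )


class TestChecklistStructure:
    def test_default_checklist_has_fifteen_items_with_valid_parents(self):
        items = default_checklist()
        assert len(items) == 15
        by_id = {i.item_id: i for i in items}
        assert {i.item_id for i in items if i.parent == "A1"} == {"A1.1", "A1.2"}
        assert {i.item_id for i in items if i.parent == "R1"} == {"R1.1", "R1.2", "R1.3"}
        for item in items:
            if item.parent:
                assert by_id[item.parent].category is item.category

    def test_cross_category_parent_rejected(self):
        items = default_checklist() + [
            ChecklistItem(item_id="X1", text="x", category=FAIRCategory.FINDABILITY, parent="A1")
        ]
        with pytest.raises(ValueError, match="different category"):
            aggregate_checklist([response()], items)

    def test_builtin_barriers_are_mandatory(self):
        with pytest.raises(ValidationError, match="limited_incentives"):
            SurveyResponse(
                respondent_id="r1",
                barriers={"limited_financial": BarrierRating.VERY_IMPORTANT},
            )


class TestValidateResponse:
    def test_conditional_item_answered_without_yes_parent(self):
        resp = response(answers={"A1": "no", "A1.1": "yes"})
        issues = validate_response(resp)
        assert len(issues) == 1
        assert issues[0].item_id == "A1.1"

    def test_consistent_response_is_clean(self):
        resp = response(answers={"A1": "yes", "A1.1": "yes", "R1": "no", "F1": "no"})
        assert validate_response(resp) == []

    def test_unknown_item_flagged(self):
        issues = validate_response(response(answers={"X9": "yes"}))
        assert len(issues) == 1
        assert issues[0].item_id == "X9"


class TestAggregateChecklist:
    def test_seven_of_ten_yes_gives_seventy_percent(self):
        resps = [
            response(rid=f"r{i}", answers={"F1": "yes" if i < 7 else "no"})
            for i in range(10)
        ]
        summary = aggregate_checklist(resps)
        assert summary.items["F1"].percent_yes == 70.0
        assert summary.items["F1"].denominator == 10

    def test_all_yes_everywhere_is_one_hundred(self):
        answers = {i.item_id: "yes" for i in default_checklist()}
        resps = [response(rid=f"r{i}", answers=answers) for i in range(4)]
        summary = aggregate_checklist(resps)
        assert all(s.percent_yes == 100.0 for s in summary.items.values())

    def test_conditional_item_uses_parent_yes_denominator(self):
        # A1 yes for 4 of 10; among those, A1.1 yes for 2.
        resps = []
        for i in range(10):
            answers = {"A1": "yes" if i < 4 else "no"}
            if i < 4:
                answers["A1.1"] = "yes" if i < 2 else "no"
            resps.append(response(rid=f"r{i}", answers=answers))
        summary = aggregate_checklist(resps)
        assert summary.items["A1.1"].percent_yes == 50.0
        assert summary.items["A1.1"].denominator == 4
        # The alternative convention divides by everyone instead.
        summary_all = aggregate_checklist(resps, conditional_denominator="all")
        assert summary_all.items["A1.1"].percent_yes == 20.0
        assert summary_all.items["A1.1"].denominator == 10

    def test_zero_denominator_is_undefined_not_zero(self):
        resps = [response(rid="r1", answers={"A1": "no"})]
        summary = aggregate_checklist(resps)
        assert summary.items["A1.1"].percent_yes is None
        assert summary.items["A1.1"].denominator == 0

    def test_blank_counts_as_not_yes_in_its_denominator(self):
        resps = [
            response(rid="r1", answers={"F1": "yes"}),
            response(rid="r2"),  # F1 left blank
        ]
        assert aggregate_checklist(resps).items["F1"].percent_yes == 50.0

    def test_empty_respondent_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_checklist([])

    def test_conditional_denominator_never_exceeds_parent_yes_count(self):
        rng = random.Random(5)
        resps = []
        for i in range(30):
            answers = {}
            for item in default_checklist():
                if item.parent is None:
                    answers[item.item_id] = rng.choice(["yes", "no"])
                elif answers.get(item.parent) == "yes":
                    answers[item.item_id] = rng.choice(["yes", "no", "blank"])
            resps.append(response(rid=f"r{i}", answers={
                k: v for k, v in answers.items() if v != "blank"
            }))
        summary = aggregate_checklist(resps)
        for item in default_checklist():
            if item.parent is not None:
                parent_yes = sum(
                    1 for r in resps if r.answer(item.parent) is Answer.YES
                )
                assert summary.items[item.item_id].denominator <= parent_yes

    def test_permutation_and_duplication_leave_percentages_unchanged(self):
        rng = random.Random(9)
        resps = [
            response(rid=f"r{i}", answers={
                "F1": rng.choice(["yes", "no"]),
                "A1": rng.choice(["yes", "no"]),
            })
            for i in range(8)
        ]
        base = aggregate_checklist(resps)
        shuffled = aggregate_checklist(list(reversed(resps)))
        doubled = aggregate_checklist(resps + resps)
        for item_id in base.items:
            assert base.items[item_id].percent_yes == shuffled.items[item_id].percent_yes
            assert base.items[item_id].percent_yes == doubled.items[item_id].percent_yes


class TestAggregateBarriers:
    def test_eight_one_one_split(self):
        ratings = (
            [BarrierRating.VERY_IMPORTANT] * 8
            + [BarrierRating.MODERATELY_IMPORTANT]
            + [BarrierRating.NOT_IMPORTANT]
        )
        resps = [
            response(rid=f"r{i}", barriers={"limited_human": r})
            for i, r in enumerate(ratings)
        ]
        b = aggregate_barriers(resps).barriers["limited_human"]
        assert (b.percent_very_important, b.percent_moderately_important,
                b.percent_not_important) == (80.0, 10.0, 10.0)

    def test_six_three_one_split(self):
        ratings = (
            [BarrierRating.VERY_IMPORTANT] * 6
            + [BarrierRating.MODERATELY_IMPORTANT] * 3
            + [BarrierRating.NOT_IMPORTANT]
        )
        resps = [
            response(rid=f"r{i}", barriers={"limited_financial": r})
            for i, r in enumerate(ratings)
        ]
        b = aggregate_barriers(resps).barriers["limited_financial"]
        assert (b.percent_very_important, b.percent_moderately_important,
                b.percent_not_important) == (60.0, 30.0, 10.0)

    def test_single_respondent_all_very_important(self):
        barriers = {name: BarrierRating.VERY_IMPORTANT for name in BARRIER_DEFAULTS}
        summary = aggregate_barriers([response(barriers=barriers)])
        for b in summary.barriers.values():
            assert (b.percent_very_important, b.percent_moderately_important,
                    b.percent_not_important) == (100.0, 0.0, 0.0)

    def test_builtin_levels_sum_to_one_hundred(self):
        rng = random.Random(3)
        resps = [
            response(rid=f"r{i}", barriers={
                name: rng.choice(list(BarrierRating)) for name in BARRIER_DEFAULTS
            })
            for i in range(10)
        ]
        for name in BARRIER_DEFAULTS:
            b = aggregate_barriers(resps).barriers[name]
            assert b.percent_very_important + b.percent_moderately_important + \
                b.percent_not_important == pytest.approx(100.0, abs=0.2)

    def test_free_text_barriers_normalized_and_aggregated(self):
        resps = [
            response(rid="r1", barriers={"Legal Barriers": BarrierRating.VERY_IMPORTANT}),
            response(rid="r2", barriers={"legal barriers": BarrierRating.NOT_IMPORTANT}),
        ]
        summary = aggregate_barriers(resps)
        assert "legal_barriers" in summary.barriers
        b = summary.barriers["legal_barriers"]
        assert b.percent_very_important == 50.0
        assert b.percent_not_important == 50.0
        assert normalize_barrier_name("  Legal  Barriers ") == "legal_barriers"


class TestResponseIO:
    def test_csv_roundtrip(self, tmp_path):
        resps = [
            response(rid="r1", answers={"F1": "yes", "A1": "yes", "A1.1": "no"},
                     barriers={"limited_human": BarrierRating.VERY_IMPORTANT,
                               "legal_barriers": BarrierRating.MODERATELY_IMPORTANT},
                     comments={"F1": "uses DOIs"}),
            response(rid="r2", answers={"F1": "no"}),
        ]
        path = tmp_path / "resps.csv"
        write_responses(resps, path)
        back = read_responses(path)
        assert [r.respondent_id for r in back] == ["r1", "r2"]
        assert back[0].answers["A1.1"] is Answer.NO
        assert back[0].comments == {"F1": "uses DOIs"}
        assert back[0].barriers["legal_barriers"] is BarrierRating.MODERATELY_IMPORTANT
        assert back[1].answer("F1") is Answer.NO
        assert back[1].answer("A1") is Answer.BLANK

    def test_structured_roundtrip(self, tmp_path):
        resps = [response(rid="r1", answers={"F1": "yes"})]
        path = tmp_path / "resps.json"
        write_responses(resps, path, format="structured")
        assert read_responses(path, format="structured") == resps
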