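"""Scoring engine: rubric, overall aggregation, classification, summaries."""

import itertools
import random

import pytest
from pydantic import ValidationError

from cdomeval.inventory import CompletenessStatus, FieldScore, NAReason
from cdomeval.schema import MetadataField, SourceType
from cdomeval.scoring import (
    Channel,
    Coverage,
    CoverageAssessment,
    UndefinedStatusError,
    aggregate_overall,
    build_summary,
    classify_study,
    count_source_availability,
    derive_field_score,
    median_field_scores,
    summarize_infrastructure,
)
from cdomeval.synthetic import GeneratorConfig, generate_inventories

from conftest import make_inventory

GROUPS = ("cardiovascular", "cancer", "type2_diabetes")


def assessment(*levels):
    return CoverageAssessment(
        study_id="s1",
        source=SourceType.SCIENTIFIC_PUBLICATIONS,
        field=MetadataField.PREVALENT_INCIDENT,
        coverage=dict(zip(GROUPS, levels)),
    )


class TestRubric:
    @pytest.mark.parametrize(
        "levels,expected",
        [
            ((Coverage.COMPLETE, Coverage.COMPLETE, Coverage.COMPLETE), 3),
            ((Coverage.COMPLETE, Coverage.ABSENT, Coverage.ABSENT), 2),
            ((Coverage.COMPLETE, Coverage.PARTIAL, Coverage.ABSENT), 2),
            ((Coverage.PARTIAL, Coverage.PARTIAL, Coverage.PARTIAL), 1),
            ((Coverage.PARTIAL, Coverage.ABSENT, Coverage.ABSENT), 1),
            ((Coverage.ABSENT, Coverage.ABSENT, Coverage.ABSENT), 0),
        ],
    )
    def test_rubric_examples(self, levels, expected):
        assert derive_field_score(assessment(*levels)).value == expected

    def test_rubric_matches_enumeration_oracle_on_all_patterns(self):
        # Independent oracle: count coverage levels and apply the verbal
        # rubric conditions directly.
        for levels in itertools.product(Coverage, repeat=3):
            n_complete = sum(c is Coverage.COMPLETE for c in levels)
            n_partial = sum(c is Coverage.PARTIAL for c in levels)
            if n_complete == 3:
                expected = 3
            elif n_complete >= 1:
                expected = 2
            elif n_partial >= 1:
                expected = 1
            else:
                expected = 0
            assert derive_field_score(assessment(*levels)).value == expected

    def test_empty_coverage_is_a_precondition_error(self):
        with pytest.raises(ValidationError):
            CoverageAssessment(
                study_id="s1",
                source=SourceType.SCIENTIFIC_PUBLICATIONS,
                field=MetadataField.PREVALENT_INCIDENT,
                coverage={},
            )


class TestAggregateOverall:
    def test_carla_prevalent_incident_takes_max_across_sources(self, fixture_by_id):
        inv = fixture_by_id["carla"]
        per_source = [
            inv.evidence[src].direct[MetadataField.PREVALENT_INCIDENT].value
            for src in SourceType
        ]
        assert per_source == [2, 1, 0, 3]
        assert aggregate_overall(inv)[MetadataField.PREVALENT_INCIDENT].value == 3

    def test_life_adult_icd10_all_zero_sources_stay_zero(self, fixture_by_id):
        inv = fixture_by_id["life_adult"]
        assert all(
            inv.evidence[src].direct[MetadataField.ICD10_AVAILABLE].value == 0
            for src in SourceType
        )
        assert aggregate_overall(inv)[MetadataField.ICD10_AVAILABLE].value == 0

    def test_all_na_field_propagates_most_informative_reason(self, fixture_by_id):
        degs1 = aggregate_overall(fixture_by_id["degs1"])
        assert degs1[MetadataField.ADMINISTRATIVE_DATABASES].na_reason is NAReason.DESIGN
        geda = aggregate_overall(fixture_by_id["geda"])
        assert geda[MetadataField.ICD10_AVAILABLE].na_reason is NAReason.FIELD_EXEMPT
        lida = aggregate_overall(fixture_by_id["lida"])
        assert lida[MetadataField.STUDY_EXAMINATIONS].na_reason is NAReason.DESIGN

    def test_field_na_only_when_every_source_na(self, fixture_inventories):
        for inv in fixture_inventories:
            overall = aggregate_overall(inv)
            for f in MetadataField:
                source_values = [inv.evidence[s].direct[f].value for s in SourceType]
                assert overall[f].is_na == all(v is None for v in source_values)


class TestClassification:
    @pytest.mark.parametrize(
        "study_id,expected",
        [
            ("kora", CompletenessStatus.COMPLETE_ALL),
            ("epic_heidelberg", CompletenessStatus.COMPLETE_SOME),
            ("hnrs", CompletenessStatus.PARTIAL),
        ],
    )
    def test_fixture_examples(self, fixture_by_id, study_id, expected):
        assert classify_study(aggregate_overall(fixture_by_id[study_id])) is expected

    def test_all_zero_scores_classify_missing(self):
        inv = make_inventory(scores=0)
        assert classify_study(aggregate_overall(inv)) is CompletenessStatus.MISSING

    def test_all_na_raises_undefined_status(self):
        inv = make_inventory(present={src: False for src in SourceType})
        with pytest.raises(UndefinedStatusError):
            classify_study(aggregate_overall(inv))

    def test_status_ordering_is_total(self):
        order = [
            CompletenessStatus.MISSING,
            CompletenessStatus.PARTIAL,
            CompletenessStatus.COMPLETE_SOME,
            CompletenessStatus.COMPLETE_ALL,
        ]
        for a, b in itertools.combinations(order, 2):
            assert a < b and b > a and a <= b


class TestMedians:
    def test_even_count_interpolates(self):
        overalls = [
            aggregate_overall(
                make_inventory(study_id=f"s{i}", scores={
                    (src, f): v for src in SourceType for f in MetadataField
                })
            )
            for i, v in enumerate([0, 2, 3, 3])
        ]
        medians = median_field_scores(overalls)
        assert medians[MetadataField.PREVALENT_INCIDENT] == 2.5

    def test_fixture_medians(self, fixture_inventories):
        overalls = [aggregate_overall(inv) for inv in fixture_inventories]
        medians = median_field_scores(overalls)
        assert medians[MetadataField.ICD10_AVAILABLE] == 2
        for f in MetadataField:
            if f is not MetadataField.ICD10_AVAILABLE:
                assert medians[f] == 3

    def test_field_na_everywhere_yields_none(self):
        overalls = [aggregate_overall(make_inventory(uses_admin=False, scores=1))]
        assert median_field_scores(overalls)[MetadataField.ADMINISTRATIVE_DATABASES] is None

    def test_empty_study_list_rejected(self):
        with pytest.raises(ValueError):
            median_field_scores([])


class TestCounts:
    def test_fixture_source_availability(self, fixture_inventories):
        counts = count_source_availability(fixture_inventories)
        assert counts == {
            SourceType.SCIENTIFIC_PUBLICATIONS: 16,
            SourceType.STUDY_WEBSITE: 15,
            SourceType.STUDY_TRIAL_REGISTRIES: 11,
            SourceType.DATA_DOCUMENTS: 10,
        }

    def test_present_but_all_zero_source_does_not_count(self, fixture_by_id):
        # HCHS's website was found but described nothing directly.
        hchs = fixture_by_id["hchs"]
        assert hchs.evidence[SourceType.STUDY_WEBSITE].present
        counts = count_source_availability([hchs])
        assert counts[SourceType.STUDY_WEBSITE] == 0
        # On the combined channel the linked metadata do count.
        assert count_source_availability([hchs], Channel.COMBINED)[SourceType.STUDY_WEBSITE] == 1

    def test_empty_input_gives_all_zeros(self):
        assert set(count_source_availability([]).values()) == {0}
        infra = summarize_infrastructure([])
        assert set(infra.values()) == {0}

    def test_fixture_infrastructure_counts(self, fixture_inventories):
        infra = summarize_infrastructure(fixture_inventories)
        assert infra == {
            "available": 11,
            "none": 5,
            "open_no_registration": 7,
            "registration_required": 3,
            "no_registration_option": 1,
        }

    def test_single_unavailable_study(self):
        infra = summarize_infrastructure([make_inventory(infra_available=False)])
        assert infra["none"] == 1 and infra["available"] == 0


class TestBuildSummary:
    def test_fixture_summary_matches_reported_statuses(self, fixture_inventories):
        report = build_summary(fixture_inventories)
        assert report.discrepancies == []
        assert report.status_tally == {
            CompletenessStatus.COMPLETE_ALL: 6,
            CompletenessStatus.COMPLETE_SOME: 4,
            CompletenessStatus.PARTIAL: 6,
            CompletenessStatus.MISSING: 0,
        }
        assert report.tally_line() == "complete_all=6 complete_some=4 partial=6 missing=0"

    def test_all_zero_inventories_tally_missing(self):
        invs = [make_inventory(study_id=f"s{i}", scores=0) for i in range(5)]
        report = build_summary(invs)
        assert report.status_tally[CompletenessStatus.MISSING] == 5

    def test_score_matrix_shape_and_median_row(self, fixture_inventories):
        report = build_summary(fixture_inventories)
        matrix = report.score_matrix(fixture_inventories)
        # 16 studies x (4 sources + overall) + median footer
        assert len(matrix) == 16 * 5 + 1
        median_row = matrix.iloc[-1]
        assert median_row["row"] == "median"
        assert median_row["icd10_available"] == "2"
        assert median_row["prevalent_incident"] == "3"


class TestInvariants:
    def test_raising_one_cell_never_lowers_overall_or_status(self, fixture_inventories):
        rng = random.Random(42)
        for _ in range(25):
            inv = rng.choice(fixture_inventories)
            src = rng.choice(list(SourceType))
            ev = inv.evidence[src]
            f = rng.choice(list(MetadataField))
            score = ev.direct[f]
            if not ev.present or score.is_na or score.value == 3:
                continue
            bumped_direct = dict(ev.direct) | {f: FieldScore.of(score.value + 1)}
            combined = ev.combined[f]
            bumped_combined = dict(ev.combined)
            if not combined.is_na and combined.value < score.value + 1:
                bumped_combined[f] = FieldScore.of(score.value + 1)
            new_ev = ev.model_copy(update={"direct": bumped_direct, "combined": bumped_combined})
            new_inv = inv.model_copy(update={"evidence": dict(inv.evidence) | {src: new_ev}})
            before, after = aggregate_overall(inv), aggregate_overall(new_inv)
            for field in MetadataField:
                if not before[field].is_na:
                    assert after[field].value >= before[field].value
            assert classify_study(after) >= classify_study(before)

    def test_combined_channel_dominates_direct(self):
        invs = generate_inventories(GeneratorConfig(seed=17, n_studies=40))
        for inv in invs:
            direct = aggregate_overall(inv, Channel.DIRECT)
            combined = aggregate_overall(inv, Channel.COMBINED)
            for f in MetadataField:
                if not direct[f].is_na:
                    assert combined[f].value >= direct[f].value

    def test_summaries_invariant_under_study_permutation(self, fixture_inventories):
        shuffled = list(fixture_inventories)
        random.Random(7).shuffle(shuffled)
        a, b = build_summary(fixture_inventories), build_summary(shuffled)
        assert a.status_tally == b.status_tally
        assert a.medians == b.medians
        assert a.source_counts == b.source_counts
        assert a.infrastructure_counts == b.infrastructure_counts
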