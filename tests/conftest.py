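import pytest

from cdomeval.inventory import (
    Accessibility,
    FieldScore,
    InfrastructureStatus,
    NAReason,
    SourceEvidence,
    Study,
    StudyDesign,
    StudyInventory,
    load_fixture,
)
from cdomeval.schema import (
    MetadataField,
    SourceType,
    StudyDesignProfile,
    applicable_fields,
)


@pytest.fixture(scope="session")
def fixture_inventories():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_by_id(fixture_inventories):
    return {inv.study_id: inv for inv in fixture_inventories}


def make_inventory(
    study_id="s1",
    *,
    uses_self_report=True,
    uses_examinations=True,
    uses_admin=True,
    exemptions=(),
    present=None,
    scores=None,
    combined_scores=None,
    infra_available=True,
    accessibility=Accessibility.OPEN_NO_REGISTRATION,
    reported=None,
):
    """Build a one-study inventory with uniform or per-(source, field) scores.

    ``scores`` is an int applied to every applicable field of every present
    source, or a dict keyed by (SourceType, MetadataField); ``combined_scores``
    overrides the combined channel the same way (defaults to direct).
    """
    profile = StudyDesignProfile(
        study_id=study_id,
        uses_self_report=uses_self_report,
        uses_examinations=uses_examinations,
        uses_admin_databases_for_ascertainment=uses_admin,
        field_exemptions=frozenset(exemptions),
    )
    applicable = applicable_fields(profile)
    present = {src: True for src in SourceType} if present is None else present

    def lookup(table, default, src, f):
        if table is None:
            return default
        if isinstance(table, int):
            return table
        return table.get((src, f), default)

    evidence = {}
    for src in SourceType:
        is_present = present.get(src, True)
        direct, combined = {}, {}
        for f in MetadataField:
            if f not in applicable:
                reason = NAReason.FIELD_EXEMPT if f in exemptions else NAReason.DESIGN
                direct[f] = combined[f] = FieldScore.na(reason)
            elif not is_present:
                direct[f] = combined[f] = FieldScore.na(NAReason.SOURCE_ABSENT)
            else:
                d = lookup(scores, 0, src, f)
                direct[f] = FieldScore.of(d)
                combined[f] = FieldScore.of(lookup(combined_scores, d, src, f))
        evidence[src] = SourceEvidence(
            study_id=study_id, source=src, present=is_present,
            direct=direct, combined=combined,
        )
    return StudyInventory(
        study=Study(
            study_id=study_id,
            name=f"Test study {study_id}",
            design=StudyDesign.COHORT,
            design_profile=profile,
        ),
        evidence=evidence,
        infrastructure=InfrastructureStatus(
            study_id=study_id,
            available=infra_available,
            accessibility=accessibility if infra_available else Accessibility.NOT_APPLICABLE,
        ),
        reported_overall_status=reported,
    )
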