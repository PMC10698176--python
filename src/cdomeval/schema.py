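"""Chronic disease outcome metadata (CDOM) schema.

A CDOM record describes *how* one chronic-disease outcome was ascertained in
one observational study: whether prevalent or incident cases were collected,
which classification system (typically ICD-10) was used, whether the outcome
was primary or secondary, and the collection method(s) — self-report, study
examinations, administrative databases — each with method-specific detail
items (interview mode and device, disease domains, reference period,
verification/validation; examination procedures and thresholds; database
sources).

The module defines

* the three built-in chronic-disease outcome groups (cardiovascular disease,
  cancer, type 2 diabetes) plus a registry for additional groups,
* the nine scored metadata fields and their paths in the published schema,
* the four public metadata-source types (scientific publications, study
  website, study/trial registries, data documents),
* :class:`CDOMRecord` — a full structured metadata description of one
  outcome, with :func:`validate_record` for cross-field consistency,
* :class:`StudyDesignProfile` and :func:`applicable_fields` — which of the
  nine fields a study's design makes assessable at all.
"""

from __future__ import annotations

import enum
import json
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "OutcomeGroup",
    "BUILTIN_OUTCOME_GROUPS",
    "register_outcome_group",
    "outcome_group",
    "MetadataField",
    "SCHEMA_PATHS",
    "FIELD_LABELS",
    "SourceType",
    "INDIRECT_CAPABLE_SOURCES",
    "can_have_indirect",
    "CDOMRecord",
    "SelfReportDetail",
    "ExaminationDetail",
    "AdministrativeDetail",
    "CollectionMethod",
    "ClassificationCode",
    "StudyDesignProfile",
    "applicable_fields",
    "ValidationIssue",
    "validate_record",
    "record_json_schema",
    "load_bundled_schema",
]


# ---------------------------------------------------------------------------
# Outcome groups
# ---------------------------------------------------------------------------

class OutcomeGroup(BaseModel):
    """A chronic-disease outcome group examined by the included studies."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str


BUILTIN_OUTCOME_GROUPS: dict[str, OutcomeGroup] = {
    "cardiovascular": OutcomeGroup(id="cardiovascular", label="Cardiovascular diseases"),
    "cancer": OutcomeGroup(id="cancer", label="Cancer"),
    "type2_diabetes": OutcomeGroup(id="type2_diabetes", label="Type 2 diabetes mellitus"),
}

_registry: dict[str, OutcomeGroup] = dict(BUILTIN_OUTCOME_GROUPS)


def register_outcome_group(id: str, label: str) -> OutcomeGroup:
    """Register an additional outcome group.

    The three built-in groups are always available; registering an id that
    collides with a built-in (or an already registered group with a different
    label) raises ``ValueError``.  Re-registering an identical group is a
    no-op.
    """
    group = OutcomeGroup(id=id, label=label)
    existing = _registry.get(id)
    if existing is not None:
        if existing == group:
            return existing
        raise ValueError(f"outcome group id {id!r} already registered as {existing.label!r}")
    _registry[id] = group
    return group


def outcome_group(id: str) -> OutcomeGroup:
    """Look up a registered outcome group by id."""
    try:
        return _registry[id]
    except KeyError:
        raise KeyError(f"unknown outcome group {id!r}; register it first") from None


# ---------------------------------------------------------------------------
# Scored metadata fields
# ---------------------------------------------------------------------------

class MetadataField(str, enum.Enum):
    """The nine scored CDOM fields, in their canonical (column) order."""

    PREVALENT_INCIDENT = "prevalent_incident"
    ICD10_AVAILABLE = "icd10_available"
    PRIMARY_SECONDARY = "primary_secondary"
    SR_MODE_DEVICE = "sr_mode_device"
    SR_DOMAIN = "sr_domain"
    SR_REFERENCE_PERIOD = "sr_reference_period"
    SR_VERIFICATION_VALIDATION = "sr_verification_validation"
    STUDY_EXAMINATIONS = "study_examinations"
    ADMINISTRATIVE_DATABASES = "administrative_databases"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def schema_path(self) -> str:
        return SCHEMA_PATHS[self]

    @property
    def label(self) -> str:
        return FIELD_LABELS[self]


#: Item path of each scored field in the published CDOM schema.
SCHEMA_PATHS: dict[MetadataField, str] = {
    MetadataField.PREVALENT_INCIDENT: "1a",
    MetadataField.ICD10_AVAILABLE: "1b",
    MetadataField.PRIMARY_SECONDARY: "1c",
    MetadataField.SR_MODE_DEVICE: "2a.i",
    MetadataField.SR_DOMAIN: "2a.ii",
    MetadataField.SR_REFERENCE_PERIOD: "2a.iii",
    MetadataField.SR_VERIFICATION_VALIDATION: "2a.iv",
    MetadataField.STUDY_EXAMINATIONS: "2b.i",
    MetadataField.ADMINISTRATIVE_DATABASES: "2c.i",
}

FIELD_LABELS: dict[MetadataField, str] = {
    MetadataField.PREVALENT_INCIDENT: "Prevalent/incident outcome",
    MetadataField.ICD10_AVAILABLE: "ICD-10 available",
    MetadataField.PRIMARY_SECONDARY: "Primary/secondary outcome",
    MetadataField.SR_MODE_DEVICE: "Self-report: mode & device",
    MetadataField.SR_DOMAIN: "Self-report: domain",
    MetadataField.SR_REFERENCE_PERIOD: "Self-report: reference period",
    MetadataField.SR_VERIFICATION_VALIDATION: "Self-report: verification/ext. validation",
    MetadataField.STUDY_EXAMINATIONS: "Study examinations",
    MetadataField.ADMINISTRATIVE_DATABASES: "Administrative databases",
}

#: The three fields every study can be scored on regardless of design.
GENERAL_FIELDS = (
    MetadataField.PREVALENT_INCIDENT,
    MetadataField.ICD10_AVAILABLE,
    MetadataField.PRIMARY_SECONDARY,
)

#: Fields that apply only when outcomes are (partly) self-reported.
SELF_REPORT_FIELDS = (
    MetadataField.SR_MODE_DEVICE,
    MetadataField.SR_DOMAIN,
    MetadataField.SR_REFERENCE_PERIOD,
    MetadataField.SR_VERIFICATION_VALIDATION,
)


# ---------------------------------------------------------------------------
# Metadata sources
# ---------------------------------------------------------------------------

class SourceType(str, enum.Enum):
    """The four public channels where CDOM may be found, in canonical order."""

    SCIENTIFIC_PUBLICATIONS = "scientific_publications"
    STUDY_WEBSITE = "study_website"
    STUDY_TRIAL_REGISTRIES = "study_trial_registries"
    DATA_DOCUMENTS = "data_documents"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def can_have_indirect(self) -> bool:
        return self in INDIRECT_CAPABLE_SOURCES


#: Sources that may also act as *indirect* channels (links/references), hence
#: carry a distinct direct+indirect ("combined") score.
INDIRECT_CAPABLE_SOURCES = frozenset(
    {SourceType.STUDY_WEBSITE, SourceType.STUDY_TRIAL_REGISTRIES}
)


def can_have_indirect(source: SourceType) -> bool:
    return source in INDIRECT_CAPABLE_SOURCES


# ---------------------------------------------------------------------------
# CDOM record (the full schema, one outcome in one study)
# ---------------------------------------------------------------------------

class PrevalenceType(str, enum.Enum):
    PREVALENT = "prevalent"
    INCIDENT = "incident"
    BOTH = "both"


class OutcomeRole(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"


class CollectionMethod(str, enum.Enum):
    SELF_REPORT = "self_report"
    STUDY_EXAMINATION = "study_examination"
    ADMINISTRATIVE_DATABASE = "administrative_database"


class ClassificationCode(BaseModel):
    """One disease classification code with its system tag (e.g. ICD-10 I21)."""

    model_config = ConfigDict(frozen=True)

    system: str = Field(min_length=1, description="Classification system, e.g. 'ICD-10'")
    code: str = Field(min_length=1, description="The code itself, e.g. 'I21'")


class SelfReportDetail(BaseModel):
    """Detail items for self-reported ascertainment (schema items 2a.i-2a.iv).

    ``mode_device`` and ``reference_period`` are open-vocabulary strings: the
    published lists are illustrative ("e.g. ..."), so canonical values such as
    ``capi``, ``cati``, ``last_12_months`` are conventions, not a closed enum.
    """

    mode_device: Optional[str] = None
    domains: list[str] = Field(default_factory=list)
    reference_period: Optional[str] = None
    verification_methods: list[str] = Field(default_factory=list)
    external_validation: Optional[str] = None


class ExaminationDetail(BaseModel):
    procedures: Optional[str] = None
    thresholds: Optional[str] = None


class AdministrativeDetail(BaseModel):
    sources: list[str] = Field(default_factory=list)


class CDOMRecord(BaseModel):
    """Full structured metadata for one chronic-disease outcome in one study."""

    study_id: str
    outcome_name: str
    outcome_group: OutcomeGroup
    prevalence_type: PrevalenceType
    classification_codes: list[ClassificationCode] = Field(default_factory=list)
    outcome_role: OutcomeRole
    collection_methods: list[CollectionMethod] = Field(min_length=1)
    self_report_detail: Optional[SelfReportDetail] = None
    examination_detail: Optional[ExaminationDetail] = None
    administrative_detail: Optional[AdministrativeDetail] = None

    @model_validator(mode="after")
    def _no_duplicate_methods(self) -> "CDOMRecord":
        if len(set(self.collection_methods)) != len(self.collection_methods):
            raise ValueError("collection_methods contains duplicates")
        return self


class ValidationIssue(BaseModel):
    """One cross-field consistency violation in a :class:`CDOMRecord`."""

    model_config = ConfigDict(frozen=True)

    field: str
    schema_path: str
    message: str

    def __str__(self) -> str:
        return f"[{self.schema_path}] {self.field}: {self.message}"


_DETAIL_RULES = (
    (CollectionMethod.SELF_REPORT, "self_report_detail", "2a"),
    (CollectionMethod.STUDY_EXAMINATION, "examination_detail", "2b"),
    (CollectionMethod.ADMINISTRATIVE_DATABASE, "administrative_detail", "2c"),
)


def validate_record(record: CDOMRecord) -> list[ValidationIssue]:
    """Check the cross-field invariants of a parsed :class:`CDOMRecord`.

    Structural problems (wrong types, unknown enum values) surface earlier as
    pydantic parse errors; this function only reports semantic issues on an
    already-parseable record.  It is pure and idempotent.
    """
    issues: list[ValidationIssue] = []
    methods = set(record.collection_methods)
    for method, attr, path in _DETAIL_RULES:
        detail = getattr(record, attr)
        if method in methods and detail is None:
            issues.append(
                ValidationIssue(
                    field=attr,
                    schema_path=path,
                    message=f"{method.value} is a collection method but {attr} is absent",
                )
            )
        elif method not in methods and detail is not None:
            issues.append(
                ValidationIssue(
                    field=attr,
                    schema_path=path,
                    message=f"{attr} given but {method.value} is not a collection method",
                )
            )
    for i, code in enumerate(record.classification_codes):
        if not code.code.strip() or not code.system.strip():
            issues.append(
                ValidationIssue(
                    field=f"classification_codes[{i}]",
                    schema_path="1b",
                    message="classification code entries must be non-empty and carry a system tag",
                )
            )
    return issues


# ---------------------------------------------------------------------------
# Study design profile and field applicability
# ---------------------------------------------------------------------------

class StudyDesignProfile(BaseModel):
    """Design facts of a study that decide which metadata fields apply.

    ``uses_admin_databases_for_ascertainment`` is true only when
    administrative databases contribute to (or complement) disease
    ascertainment; databases consulted solely to verify individual
    self-reported cases do not count.  ``field_exemptions`` records per-study
    exemptions of individual fields that the general design rules would make
    applicable (the fixture needs this for GEDA, where ICD-10 availability and
    self-report verification/validation are marked not applicable in print
    without a stated general rule).
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    uses_self_report: bool = True
    uses_examinations: bool = True
    uses_admin_databases_for_ascertainment: bool = True
    collects_incident_outcomes: bool = True
    field_exemptions: frozenset[MetadataField] = frozenset()


def applicable_fields(profile: StudyDesignProfile) -> frozenset[MetadataField]:
    """The metadata fields a study's design makes assessable.

    The three general-information fields always apply; the four self-report
    fields apply iff the study ascertains outcomes by self-report; study
    examinations / administrative databases apply iff the corresponding
    ascertainment route is part of the design.  Per-study exemptions are then
    removed.
    """
    fields: set[MetadataField] = set(GENERAL_FIELDS)
    if profile.uses_self_report:
        fields.update(SELF_REPORT_FIELDS)
    if profile.uses_examinations:
        fields.add(MetadataField.STUDY_EXAMINATIONS)
    if profile.uses_admin_databases_for_ascertainment:
        fields.add(MetadataField.ADMINISTRATIVE_DATABASES)
    return frozenset(fields - profile.field_exemptions)


# ---------------------------------------------------------------------------
# Machine-readable schema document
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "1.0"


def record_json_schema() -> dict:
    """JSON Schema for :class:`CDOMRecord` (generated from the data model)."""
    schema = CDOMRecord.model_json_schema()
    schema["$id"] = f"https://cdomeval.invalid/cdom_record/v{SCHEMA_VERSION}"
    schema["version"] = SCHEMA_VERSION
    return schema


def load_bundled_schema() -> dict:
    """The versioned schema document shipped with the package."""
    text = resources.files("cdomeval.data").joinpath("cdom_record.schema.json").read_text("utf-8")
    return json.loads(text)
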