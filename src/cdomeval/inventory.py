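"""Study inventories: per-study × per-source × per-field completeness evidence.

A :class:`StudyInventory` bundles everything recorded about one study during
the metadata audit: the study roster entry (design, sample size, recruitment),
one :class:`SourceEvidence` per public metadata source holding the ordinal
completeness score of every metadata field on the *direct* channel (metadata
embedded in the source) and the *combined* direct+indirect channel (metadata
reachable through links and references), the status of the study's
(meta-)data access infrastructure, and — for the packaged audit fixture — the
overall completeness status reported in print, kept for cross-checking.

Two interchange formats are supported: a flat CSV (one row per study ×
source, score columns in canonical field order, NA spelled ``na:<reason>``)
and a structured JSON/YAML document.  ``read(write(x)) == x`` field for
field, NA reasons included.

The packaged fixture transcribes the published audit of 16 German
population-based observational studies; :func:`load_fixture` assembles it and
verifies file checksums.
"""

from __future__ import annotations

import csv
import enum
import hashlib
import io
import json
import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .schema import (
    INDIRECT_CAPABLE_SOURCES,
    MetadataField,
    SourceType,
    StudyDesignProfile,
    applicable_fields,
)

__all__ = [
    "NAReason",
    "FieldScore",
    "StudyDesign",
    "Study",
    "SourceEvidence",
    "Accessibility",
    "InfrastructureStatus",
    "CompletenessStatus",
    "StudyInventory",
    "InventoryIssue",
    "InventoryWarning",
    "FormatError",
    "DuplicateKeyError",
    "FixtureIntegrityError",
    "read_inventories",
    "write_inventories",
    "load_fixture",
    "validate_inventory",
]

SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """The input file does not conform to the documented dialect."""


class DuplicateKeyError(FormatError):
    """The same (study, source) or (study, source, field) cell occurs twice."""


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


class InventoryWarning(UserWarning):
    """Non-fatal data-quality finding while reading or validating inventories."""


# ---------------------------------------------------------------------------
# Scores and statuses
# ---------------------------------------------------------------------------

class NAReason(str, enum.Enum):
    """Why a field score is not applicable.

    ``design``        — the study's design rules the field out (e.g. no
                        administrative ascertainment);
    ``source_absent`` — the metadata source itself was not found for the
                        study, so no field could be scored in it;
    ``field_exempt``  — a per-study exemption of an otherwise applicable
                        field.
    """

    DESIGN = "design"
    SOURCE_ABSENT = "source_absent"
    FIELD_EXEMPT = "field_exempt"


class FieldScore(BaseModel):
    """Ordinal completeness of one metadata field: 0-3 points, or NA.

    3 — complete description for all examined outcomes;
    2 — complete for some but not all outcomes;
    1 — partial description (details missing);
    0 — nothing found.
    """

    model_config = ConfigDict(frozen=True)

    value: Optional[int] = Field(default=None, ge=0, le=3)
    na_reason: Optional[NAReason] = None

    @model_validator(mode="after")
    def _na_consistency(self) -> "FieldScore":
        if (self.value is None) != (self.na_reason is not None):
            raise ValueError("na_reason must be present exactly when value is NA")
        return self

    @property
    def is_na(self) -> bool:
        return self.value is None

    @classmethod
    def of(cls, value: int) -> "FieldScore":
        return _SCORE_CACHE[value]

    @classmethod
    def na(cls, reason: NAReason) -> "FieldScore":
        return _NA_CACHE[reason]

    def __str__(self) -> str:
        return f"na:{self.na_reason.value}" if self.is_na else str(self.value)


# The 7 possible scores are frozen; interning them makes bulk construction
# (synthetic data at n in the thousands) cheap.
_SCORE_CACHE = {v: FieldScore(value=v) for v in range(4)}
_NA_CACHE = {r: FieldScore(value=None, na_reason=r) for r in NAReason}


class CompletenessStatus(str, enum.Enum):
    """Study-level completeness class, totally ordered missing < ... < complete_all."""

    MISSING = "missing"
    PARTIAL = "partial"
    COMPLETE_SOME = "complete_some"
    COMPLETE_ALL = "complete_all"

    @property
    def rank(self) -> int:
        return _STATUS_RANK[self]

    def __lt__(self, other: object):  # type: ignore[override]
        if isinstance(other, CompletenessStatus):
            return self.rank < other.rank
        return NotImplemented

    def __le__(self, other: object):  # type: ignore[override]
        if isinstance(other, CompletenessStatus):
            return self.rank <= other.rank
        return NotImplemented

    def __gt__(self, other: object):  # type: ignore[override]
        if isinstance(other, CompletenessStatus):
            return self.rank > other.rank
        return NotImplemented

    def __ge__(self, other: object):  # type: ignore[override]
        if isinstance(other, CompletenessStatus):
            return self.rank >= other.rank
        return NotImplemented

    @property
    def label(self) -> str:
        return _STATUS_LABELS[self]


_STATUS_RANK = {
    CompletenessStatus.MISSING: 0,
    CompletenessStatus.PARTIAL: 1,
    CompletenessStatus.COMPLETE_SOME: 2,
    CompletenessStatus.COMPLETE_ALL: 3,
}

_STATUS_LABELS = {
    CompletenessStatus.MISSING: "Metadata missing",
    CompletenessStatus.PARTIAL: "Partial metadata",
    CompletenessStatus.COMPLETE_SOME: "Complete metadata for some outcomes",
    CompletenessStatus.COMPLETE_ALL: "Complete metadata for all outcomes",
}


# ---------------------------------------------------------------------------
# Study roster, evidence, infrastructure
# ---------------------------------------------------------------------------

class StudyDesign(str, enum.Enum):
    COHORT = "cohort"
    CROSS_SECTIONAL = "cross_sectional"
    MIXED = "mixed"
    REPEATED_CROSS_SECTIONAL = "repeated_cross_sectional"


class Study(BaseModel):
    """Roster entry for one included study."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    name: str
    design: StudyDesign
    sample_size_text: str = ""
    recruitment_years: str = ""
    age_at_recruitment: str = ""
    design_profile: StudyDesignProfile

    @model_validator(mode="after")
    def _ids_match(self) -> "Study":
        if self.design_profile.study_id != self.study_id:
            raise ValueError("design_profile.study_id must equal study_id")
        return self


class SourceEvidence(BaseModel):
    """Scores recorded for one study in one metadata source.

    ``direct`` and ``combined`` map every one of the nine fields to a
    :class:`FieldScore`; inapplicable fields are NA with reason ``design`` or
    ``field_exempt``, and when the source itself was not found (``present``
    false) the remaining fields are NA with reason ``source_absent``.  For
    sources that cannot act as indirect channels, ``combined`` mirrors
    ``direct``.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    source: SourceType
    present: bool
    direct: dict[MetadataField, FieldScore]
    combined: dict[MetadataField, FieldScore]

    @model_validator(mode="after")
    def _structure(self) -> "SourceEvidence":
        all_fields = set(MetadataField)
        for name, mapping in (("direct", self.direct), ("combined", self.combined)):
            if set(mapping) != all_fields:
                raise ValueError(f"{name} must map every metadata field")
        if not self.present:
            for mapping in (self.direct, self.combined):
                for f, s in mapping.items():
                    if not s.is_na:
                        raise ValueError(
                            f"source {self.source.value} marked absent but {f.value} has a score"
                        )
        return self

    def score(self, field: MetadataField, channel: str = "direct") -> FieldScore:
        return (self.direct if channel == "direct" else self.combined)[field]


class Accessibility(str, enum.Enum):
    OPEN_NO_REGISTRATION = "open_no_registration"
    REGISTRATION_REQUIRED = "registration_required"
    NO_REGISTRATION_OPTION = "no_registration_option"
    NOT_APPLICABLE = "not_applicable"


class InfrastructureStatus(BaseModel):
    """Availability and accessibility of a study's (meta-)data access portal."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    available: bool
    accessibility: Accessibility

    @model_validator(mode="after")
    def _consistency(self) -> "InfrastructureStatus":
        if (self.accessibility is Accessibility.NOT_APPLICABLE) == self.available:
            raise ValueError("accessibility must be not_applicable exactly when unavailable")
        return self


class StudyInventory(BaseModel):
    """Everything recorded about one study in the metadata audit."""

    model_config = ConfigDict(frozen=True)

    study: Study
    evidence: dict[SourceType, SourceEvidence]
    infrastructure: InfrastructureStatus
    reported_overall_status: Optional[CompletenessStatus] = None

    @model_validator(mode="after")
    def _structure(self) -> "StudyInventory":
        if set(self.evidence) != set(SourceType):
            raise ValueError("evidence must contain exactly one entry per source type")
        for src, ev in self.evidence.items():
            if ev.source is not src:
                raise ValueError(f"evidence[{src.value}] has mismatched source {ev.source.value}")
            if ev.study_id != self.study.study_id:
                raise ValueError("evidence study_id mismatch")
        if self.infrastructure.study_id != self.study.study_id:
            raise ValueError("infrastructure study_id mismatch")
        return self

    @property
    def study_id(self) -> str:
        return self.study.study_id


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

class InventoryIssue(BaseModel):
    """One data-quality finding in an inventory, localised to a cell."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    source: Optional[SourceType] = None
    field: Optional[MetadataField] = None
    message: str

    def __str__(self) -> str:
        where = self.study_id
        if self.source is not None:
            where += f"/{self.source.value}"
        if self.field is not None:
            where += f"/{self.field.value}"
        return f"{where}: {self.message}"


def validate_inventory(inv: StudyInventory) -> list[InventoryIssue]:
    """Report data-quality warnings for one inventory.

    Checked: combined < direct cells (the combined channel can only add
    information, so these flag suspected errata in the underlying audit),
    scores on fields the study's design makes inapplicable, and NA-reason
    inconsistencies relative to the design profile and source presence.
    Findings are warnings, not errors — the printed record is preserved as-is.
    """
    issues: list[InventoryIssue] = []
    applicable = applicable_fields(inv.study.design_profile)
    exemptions = inv.study.design_profile.field_exemptions
    for src in SourceType:
        ev = inv.evidence[src]
        for f in MetadataField:
            d, c = ev.direct[f], ev.combined[f]
            if not d.is_na and not c.is_na and c.value < d.value:
                issues.append(
                    InventoryIssue(
                        study_id=inv.study_id,
                        source=src,
                        field=f,
                        message=f"combined score {c.value} below direct score {d.value}",
                    )
                )
            if f not in applicable:
                expected = (
                    NAReason.FIELD_EXEMPT if f in exemptions else NAReason.DESIGN
                )
                for channel, s in (("direct", d), ("combined", c)):
                    if not s.is_na:
                        issues.append(
                            InventoryIssue(
                                study_id=inv.study_id,
                                source=src,
                                field=f,
                                message=f"{channel} score on inapplicable field "
                                f"(expected na:{expected.value})",
                            )
                        )
            elif not ev.present:
                for channel, s in (("direct", d), ("combined", c)):
                    if s.na_reason is not NAReason.SOURCE_ABSENT:
                        issues.append(
                            InventoryIssue(
                                study_id=inv.study_id,
                                source=src,
                                field=f,
                                message=f"{channel} entry in absent source should be "
                                "na:source_absent",
                            )
                        )
    return issues


# ---------------------------------------------------------------------------
# Flat CSV dialect
# ---------------------------------------------------------------------------

_STUDY_COLUMNS = [
    "study_id",
    "name",
    "design",
    "sample_size_text",
    "recruitment_years",
    "age_at_recruitment",
    "uses_self_report",
    "uses_examinations",
    "uses_admin_databases",
    "collects_incident_outcomes",
    "field_exemptions",
    "infra_available",
    "infra_accessibility",
    "reported_overall_status",
]

_FIELD_ORDER = list(MetadataField)
_SCORE_COLUMNS = [f"{f.value}_{ch}" for f in _FIELD_ORDER for ch in ("direct", "combined")]
CSV_HEADER = _STUDY_COLUMNS + ["source", "present"] + _SCORE_COLUMNS


def _score_to_cell(score: FieldScore) -> str:
    return str(score)


def _cell_to_score(cell: str, where: str) -> FieldScore:
    cell = cell.strip()
    if cell.startswith("na:"):
        try:
            return FieldScore.na(NAReason(cell[3:]))
        except ValueError:
            raise FormatError(f"{where}: unknown NA reason in {cell!r}") from None
    try:
        value = int(cell)
    except ValueError:
        raise FormatError(f"{where}: expected score 0-3 or na:<reason>, got {cell!r}") from None
    if not 0 <= value <= 3:
        raise FormatError(f"{where}: score {value} out of range 0-3")
    return FieldScore.of(value)


def _bool_to_cell(b: bool) -> str:
    return "true" if b else "false"


def _cell_to_bool(cell: str, where: str) -> bool:
    c = cell.strip().lower()
    if c in {"true", "1", "yes"}:
        return True
    if c in {"false", "0", "no"}:
        return False
    raise FormatError(f"{where}: expected boolean, got {cell!r}")


def _inventory_rows(inv: StudyInventory) -> Iterable[list[str]]:
    s, p = inv.study, inv.study.design_profile
    study_cells = [
        s.study_id,
        s.name,
        s.design.value,
        s.sample_size_text,
        s.recruitment_years,
        s.age_at_recruitment,
        _bool_to_cell(p.uses_self_report),
        _bool_to_cell(p.uses_examinations),
        _bool_to_cell(p.uses_admin_databases_for_ascertainment),
        _bool_to_cell(p.collects_incident_outcomes),
        ";".join(sorted(f.value for f in p.field_exemptions)),
        _bool_to_cell(inv.infrastructure.available),
        inv.infrastructure.accessibility.value,
        inv.reported_overall_status.value if inv.reported_overall_status else "",
    ]
    for src in SourceType:
        ev = inv.evidence[src]
        row = study_cells + [src.value, _bool_to_cell(ev.present)]
        for f in _FIELD_ORDER:
            row.append(_score_to_cell(ev.direct[f]))
            row.append(_score_to_cell(ev.combined[f]))
        yield row


def _write_csv(inventories: list[StudyInventory], fh: io.TextIOBase) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for inv in inventories:
        writer.writerows(_inventory_rows(inv))


def _read_csv(fh: io.TextIOBase, name: str) -> list[StudyInventory]:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{name}: empty file, header row is mandatory") from None
    missing = [c for c in CSV_HEADER if c not in header]
    if missing:
        raise FormatError(f"{name}: missing required columns: {', '.join(missing)}")
    idx = {c: header.index(c) for c in CSV_HEADER}

    per_study: dict[str, dict] = {}
    order: list[str] = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        where = f"{name}:line {lineno}"
        if len(row) < len(header):
            raise FormatError(f"{where}: expected {len(header)} cells, got {len(row)}")

        def cell(col: str) -> str:
            return row[idx[col]]

        study_id = cell("study_id").strip()
        if not study_id:
            raise FormatError(f"{where}: empty study_id")
        try:
            source = SourceType(cell("source").strip())
        except ValueError:
            raise FormatError(f"{where}: unknown source {cell('source')!r}") from None

        if study_id not in per_study:
            order.append(study_id)
            exemptions = frozenset(
                MetadataField(tok)
                for tok in cell("field_exemptions").split(";")
                if tok.strip()
            )
            profile = StudyDesignProfile(
                study_id=study_id,
                uses_self_report=_cell_to_bool(cell("uses_self_report"), where),
                uses_examinations=_cell_to_bool(cell("uses_examinations"), where),
                uses_admin_databases_for_ascertainment=_cell_to_bool(
                    cell("uses_admin_databases"), where
                ),
                collects_incident_outcomes=_cell_to_bool(
                    cell("collects_incident_outcomes"), where
                ),
                field_exemptions=exemptions,
            )
            reported = cell("reported_overall_status").strip()
            per_study[study_id] = {
                "study": Study(
                    study_id=study_id,
                    name=cell("name"),
                    design=StudyDesign(cell("design").strip()),
                    sample_size_text=cell("sample_size_text"),
                    recruitment_years=cell("recruitment_years"),
                    age_at_recruitment=cell("age_at_recruitment"),
                    design_profile=profile,
                ),
                "infrastructure": InfrastructureStatus(
                    study_id=study_id,
                    available=_cell_to_bool(cell("infra_available"), where),
                    accessibility=Accessibility(cell("infra_accessibility").strip()),
                ),
                "reported": CompletenessStatus(reported) if reported else None,
                "evidence": {},
            }
        entry = per_study[study_id]
        if source in entry["evidence"]:
            raise DuplicateKeyError(f"{where}: duplicate ({study_id}, {source.value}) row")

        direct: dict[MetadataField, FieldScore] = {}
        combined: dict[MetadataField, FieldScore] = {}
        for f in _FIELD_ORDER:
            direct[f] = _cell_to_score(cell(f"{f.value}_direct"), f"{where} {f.value}_direct")
            combined[f] = _cell_to_score(
                cell(f"{f.value}_combined"), f"{where} {f.value}_combined"
            )
        entry["evidence"][source] = SourceEvidence(
            study_id=study_id,
            source=source,
            present=_cell_to_bool(cell("present"), where),
            direct=direct,
            combined=combined,
        )

    inventories = []
    for study_id in order:
        entry = per_study[study_id]
        missing_sources = set(SourceType) - set(entry["evidence"])
        if missing_sources:
            raise FormatError(
                f"{name}: study {study_id} lacks rows for "
                + ", ".join(sorted(s.value for s in missing_sources))
            )
        inventories.append(
            StudyInventory(
                study=entry["study"],
                evidence=entry["evidence"],
                infrastructure=entry["infrastructure"],
                reported_overall_status=entry["reported"],
            )
        )
    return inventories


# ---------------------------------------------------------------------------
# Structured (JSON/YAML) format
# ---------------------------------------------------------------------------

def _to_document(inventories: list[StudyInventory]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "studies": [inv.model_dump(mode="json") for inv in inventories],
    }


def _from_document(doc: dict, name: str) -> list[StudyInventory]:
    if not isinstance(doc, dict) or "studies" not in doc:
        raise FormatError(f"{name}: structured document must have a 'studies' key")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"{name}: unsupported schema_version {version!r}")
    out = []
    seen: set[str] = set()
    for i, item in enumerate(doc["studies"]):
        inv = StudyInventory.model_validate(item)
        if inv.study_id in seen:
            raise DuplicateKeyError(f"{name}: duplicate study {inv.study_id}")
        seen.add(inv.study_id)
        out.append(inv)
    return out


# ---------------------------------------------------------------------------
# Public IO surface
# ---------------------------------------------------------------------------

def _is_yaml(path: Path) -> bool:
    return path.suffix.lower() in {".yaml", ".yml"}


def write_inventories(
    inventories: list[StudyInventory],
    path: Union[str, Path],
    format: str = "csv",
) -> None:
    """Serialize inventories to ``path`` as ``csv`` or ``structured``.

    The structured format is YAML when the filename ends in .yaml/.yml, JSON
    otherwise.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            _write_csv(inventories, fh)
    elif format == "structured":
        doc = _to_document(inventories)
        with path.open("w", encoding="utf-8") as fh:
            if _is_yaml(path):
                yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
            else:
                json.dump(doc, fh, indent=1, ensure_ascii=False)
                fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_inventories(
    path: Union[str, Path],
    format: str = "csv",
    warn: bool = True,
) -> list[StudyInventory]:
    """Read inventories from ``path``; emit :class:`InventoryWarning` per finding.

    Data-quality findings (combined < direct cells, NA-reason inconsistencies,
    scores on inapplicable fields) do not abort the read: the file parses and
    each finding is surfaced through the ``warnings`` machinery, naming the
    cell.  Structural problems raise :class:`FormatError` /
    :class:`DuplicateKeyError`.
    """
    path = Path(path)
    if format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            inventories = _read_csv(fh, path.name)
    elif format == "structured":
        with path.open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) if _is_yaml(path) else json.load(fh)
        inventories = _from_document(doc, path.name)
    else:
        raise ValueError(f"unknown format {format!r}")
    if warn:
        for inv in inventories:
            for issue in validate_inventory(inv):
                warnings.warn(str(issue), InventoryWarning, stacklevel=2)
    return inventories


# ---------------------------------------------------------------------------
# Packaged fixture (printed audit of the 16 included studies)
# ---------------------------------------------------------------------------

_FIXTURE_FILES = ("table1_studies.csv", "table5_status.csv", "table6_scores.csv")

# Printed cells look like "3", "1 (3)" or "na."
_CELL_RE = re.compile(r"^\s*(?:(?P<na>na\.?)|(?P<direct>[0-3])(?:\s*\(\s*(?P<combined>[0-3])\s*\))?)\s*$")


def _fixture_text(filename: str) -> str:
    return resources.files("cdomeval.data").joinpath(filename).read_text("utf-8")


def _verify_checksums() -> None:
    recorded = json.loads(_fixture_text("checksums.json"))
    for filename in _FIXTURE_FILES:
        digest = hashlib.sha256(_fixture_text(filename).encode("utf-8")).hexdigest()
        if recorded.get(filename) != digest:
            raise FixtureIntegrityError(
                f"packaged fixture file {filename} fails its checksum "
                f"(expected {recorded.get(filename)}, got {digest})"
            )


def _parse_printed_cell(cell: str, where: str) -> tuple[Optional[int], Optional[int]]:
    m = _CELL_RE.match(cell)
    if not m:
        raise FormatError(f"{where}: unparseable printed cell {cell!r}")
    if m.group("na"):
        return None, None
    direct = int(m.group("direct"))
    combined = int(m.group("combined")) if m.group("combined") is not None else None
    return direct, combined


def load_fixture() -> list[StudyInventory]:
    """Assemble the packaged audit fixture of the 16 included studies.

    Scores equal the printed values: ``direct`` carries the bare numbers,
    ``combined`` the parenthetical direct+indirect numbers where printed and
    mirrors ``direct`` otherwise.  A whole-source row of "na." means the
    source was not found (``present`` false, NA reason ``source_absent``);
    per-field "na." inside a present source reflects design inapplicability
    or a per-study field exemption, as encoded in the roster's design
    profiles.  File checksums are verified before parsing.
    """
    _verify_checksums()

    profiles: dict[str, StudyDesignProfile] = {}
    studies: dict[str, Study] = {}
    order: list[str] = []
    reader = csv.DictReader(io.StringIO(_fixture_text("table1_studies.csv")))
    for row in reader:
        study_id = row["study_id"]
        order.append(study_id)
        exemptions = frozenset(
            MetadataField(tok) for tok in row["field_exemptions"].split(";") if tok.strip()
        )
        profile = StudyDesignProfile(
            study_id=study_id,
            uses_self_report=row["uses_self_report"] == "true",
            uses_examinations=row["uses_examinations"] == "true",
            uses_admin_databases_for_ascertainment=row["uses_admin_databases"] == "true",
            collects_incident_outcomes=row["collects_incident_outcomes"] == "true",
            field_exemptions=exemptions,
        )
        profiles[study_id] = profile
        studies[study_id] = Study(
            study_id=study_id,
            name=row["name"],
            design=StudyDesign(row["design"]),
            sample_size_text=row["sample_size_text"],
            recruitment_years=row["recruitment_years"],
            age_at_recruitment=row["age_at_recruitment"],
            design_profile=profile,
        )

    infra: dict[str, InfrastructureStatus] = {}
    reported: dict[str, CompletenessStatus] = {}
    for row in csv.DictReader(io.StringIO(_fixture_text("table5_status.csv"))):
        study_id = row["study_id"]
        infra[study_id] = InfrastructureStatus(
            study_id=study_id,
            available=row["infrastructure_available"] == "true",
            accessibility=Accessibility(row["accessibility"]),
        )
        reported[study_id] = CompletenessStatus(row["overall_status"])

    evidence: dict[str, dict[SourceType, SourceEvidence]] = {sid: {} for sid in order}
    for row in csv.DictReader(io.StringIO(_fixture_text("table6_scores.csv"))):
        study_id = row["study_id"]
        source = SourceType(row["source"])
        profile = profiles[study_id]
        applicable = applicable_fields(profile)
        parsed = {
            f: _parse_printed_cell(row[f.value], f"{study_id}/{source.value}/{f.value}")
            for f in MetadataField
        }
        present = any(d is not None for d, _ in parsed.values())
        direct: dict[MetadataField, FieldScore] = {}
        combined: dict[MetadataField, FieldScore] = {}
        for f, (d, c) in parsed.items():
            if f not in applicable:
                reason = (
                    NAReason.FIELD_EXEMPT
                    if f in profile.field_exemptions
                    else NAReason.DESIGN
                )
                direct[f] = combined[f] = FieldScore.na(reason)
            elif d is None:
                direct[f] = combined[f] = FieldScore.na(NAReason.SOURCE_ABSENT)
            else:
                direct[f] = FieldScore.of(d)
                if source in INDIRECT_CAPABLE_SOURCES and c is not None:
                    combined[f] = FieldScore.of(c)
                else:
                    combined[f] = FieldScore.of(d)
        evidence[study_id][source] = SourceEvidence(
            study_id=study_id, source=source, present=present, direct=direct, combined=combined
        )

    return [
        StudyInventory(
            study=studies[sid],
            evidence=evidence[sid],
            infrastructure=infra[sid],
            reported_overall_status=reported[sid],
        )
        for sid in order
    ]
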