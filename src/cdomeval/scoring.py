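"""Completeness scoring: rubric, aggregation, classification, summaries.

The ordinal rubric assigns each metadata field, within one study and one
metadata source, a score from the coverage observed per examined outcome
group:

* 3 — a complete description was found for *all* examined outcome groups;
* 2 — complete for at least one but not all groups;
* 1 — no group complete, but a partial description for at least one group;
* 0 — nothing found for any group.

Per study, a field's *overall* score is the highest score it reached in any
of the four sources (the audit's channel of record is the direct channel;
the direct+indirect "combined" channel is available as a switch).  The study
is then classified from its applicable overall scores: all 3s → complete for
all outcomes; minimum 2 → complete for some outcomes; everything 0 →
missing; anything else → partial.  Field-wise medians across studies, source
availability counts and infrastructure counts summarise the audit.
"""

from __future__ import annotations

import enum
import statistics
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .inventory import (
    Accessibility,
    CompletenessStatus,
    FieldScore,
    InventoryIssue,
    NAReason,
    StudyInventory,
    validate_inventory,
)
from .schema import MetadataField, SourceType

__all__ = [
    "Channel",
    "Coverage",
    "CoverageAssessment",
    "OverallFieldScores",
    "derive_field_score",
    "aggregate_overall",
    "classify_study",
    "median_field_scores",
    "count_source_availability",
    "summarize_infrastructure",
    "AssessmentReport",
    "StudyResult",
    "build_summary",
    "UndefinedStatusError",
]


class UndefinedStatusError(ValueError):
    """A study with no applicable (non-NA) overall field score cannot be classified."""


class Channel(str, enum.Enum):
    """Which evidence channel feeds aggregation: direct only, or direct+indirect."""

    DIRECT = "direct"
    COMBINED = "combined"


class Coverage(str, enum.Enum):
    """How completely one field was described for one outcome group."""

    COMPLETE = "complete"
    PARTIAL = "partial"
    ABSENT = "absent"


class CoverageAssessment(BaseModel):
    """Raw coverage of one field, per examined outcome group, in one source."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    source: SourceType
    field: MetadataField
    coverage: dict[str, Coverage]
    channel: Channel = Channel.DIRECT

    @model_validator(mode="after")
    def _non_empty(self) -> "CoverageAssessment":
        if not self.coverage:
            raise ValueError("coverage must list at least one examined outcome group")
        return self


def score_coverage(levels: Sequence[Coverage]) -> int:
    """The rubric core: ordinal score from per-group coverage levels."""
    if all(c is Coverage.COMPLETE for c in levels):
        return 3
    if any(c is Coverage.COMPLETE for c in levels):
        return 2
    if any(c is Coverage.PARTIAL for c in levels):
        return 1
    return 0


def derive_field_score(assessment: CoverageAssessment) -> FieldScore:
    """Apply the ordinal rubric to per-outcome-group coverage."""
    return FieldScore.of(score_coverage(list(assessment.coverage.values())))


class OverallFieldScores(BaseModel):
    """Per-study overall (max-across-sources) score for each metadata field."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    scores: dict[MetadataField, FieldScore]

    def __getitem__(self, field: MetadataField) -> FieldScore:
        return self.scores[field]

    @property
    def non_na_values(self) -> list[int]:
        return [s.value for s in self.scores.values() if s.value is not None]


#: When every source is NA for a field, the most informative reason wins:
#: a design/exemption NA persists across sources, a source-absent NA is local.
_NA_PRIORITY = (NAReason.DESIGN, NAReason.FIELD_EXEMPT, NAReason.SOURCE_ABSENT)


def aggregate_overall(
    inv: StudyInventory, channel: Channel = Channel.DIRECT
) -> OverallFieldScores:
    """Overall rating per field: the maximum non-NA score over the four sources.

    A field is NA overall only when it is NA in every source; the propagated
    reason prefers design/exemption (which hold study-wide) over source
    absence.
    """
    scores: dict[MetadataField, FieldScore] = {}
    for f in MetadataField:
        per_source = [inv.evidence[src].score(f, channel.value) for src in SourceType]
        values = [s.value for s in per_source if s.value is not None]
        if values:
            scores[f] = FieldScore.of(max(values))
        else:
            reasons = {s.na_reason for s in per_source}
            reason = next(r for r in _NA_PRIORITY if r in reasons)
            scores[f] = FieldScore.na(reason)
    return OverallFieldScores(study_id=inv.study_id, scores=scores)


def classify_study(overall: OverallFieldScores) -> CompletenessStatus:
    """Classify a study from its applicable overall field scores.

    Over the non-NA fields: everything 0 → missing; minimum 3 → complete for
    all outcomes; minimum 2 → complete for some outcomes; otherwise partial.
    """
    values = overall.non_na_values
    if not values:
        raise UndefinedStatusError(
            f"study {overall.study_id}: every field is NA, status undefined"
        )
    if max(values) == 0:
        return CompletenessStatus.MISSING
    lo = min(values)
    if lo == 3:
        return CompletenessStatus.COMPLETE_ALL
    if lo == 2:
        return CompletenessStatus.COMPLETE_SOME
    return CompletenessStatus.PARTIAL


def median_field_scores(
    all_overall: Sequence[OverallFieldScores],
) -> dict[MetadataField, Optional[float]]:
    """Field-wise median of non-NA overall scores across studies.

    Standard median (mean of the two central values for even counts); NA
    entries are excluded from the denominator.  A field NA in every study
    yields ``None``.
    """
    if not all_overall:
        raise ValueError("median requires at least one study")
    out: dict[MetadataField, Optional[float]] = {}
    for f in MetadataField:
        values = [o[f].value for o in all_overall if o[f].value is not None]
        out[f] = float(statistics.median(values)) if values else None
    return out


def count_source_availability(
    invs: Sequence[StudyInventory], channel: Channel = Channel.DIRECT
) -> dict[SourceType, int]:
    """Per source, how many studies have any metadata in it.

    A source counts for a study only when it is present *and* carries at
    least one strictly positive field score on the chosen channel — a source
    that was found but described nothing contributes no metadata.
    """
    counts = {src: 0 for src in SourceType}
    for inv in invs:
        for src in SourceType:
            ev = inv.evidence[src]
            if not ev.present:
                continue
            mapping = ev.direct if channel is Channel.DIRECT else ev.combined
            if any(s.value is not None and s.value > 0 for s in mapping.values()):
                counts[src] += 1
    return counts


def summarize_infrastructure(invs: Sequence[StudyInventory]) -> dict[str, int]:
    """Counts of (meta-)data access infrastructure availability/accessibility.

    Keys: ``available``, ``none``, and one per accessibility category; the
    categories plus ``none`` partition the studies.
    """
    out: dict[str, int] = {"available": 0, "none": 0}
    for acc in Accessibility:
        if acc is not Accessibility.NOT_APPLICABLE:
            out[acc.value] = 0
    for inv in invs:
        infra = inv.infrastructure
        if infra.available:
            out["available"] += 1
            out[infra.accessibility.value] += 1
        else:
            out["none"] += 1
    return out


# ---------------------------------------------------------------------------
# Full assessment report
# ---------------------------------------------------------------------------

class StudyResult(BaseModel):
    """Scores and derived status for one study."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    overall: OverallFieldScores
    status: CompletenessStatus
    reported_status: Optional[CompletenessStatus] = None

    @property
    def discrepant(self) -> bool:
        return self.reported_status is not None and self.reported_status != self.status


class AssessmentReport(BaseModel):
    """Complete audit summary over a set of study inventories."""

    model_config = ConfigDict(frozen=True)

    channel: Channel
    results: list[StudyResult]
    medians: dict[MetadataField, Optional[float]]
    source_counts: dict[SourceType, int]
    infrastructure_counts: dict[str, int]
    status_tally: dict[CompletenessStatus, int]
    discrepancies: list[str]
    warnings: list[InventoryIssue]

    @property
    def n_studies(self) -> int:
        return len(self.results)

    def score_matrix(self, invs: Sequence[StudyInventory]) -> pd.DataFrame:
        """Score table shaped like the published matrix: one row per study ×
        source plus an Overall row, one column per field, plus a Median row."""
        rows = []
        by_id = {r.study_id: r for r in self.results}
        for inv in invs:
            for src in SourceType:
                ev = inv.evidence[src]
                row = {"study_id": inv.study_id, "row": src.value}
                for f in MetadataField:
                    d, c = ev.direct[f], ev.combined[f]
                    cell = str(d)
                    if src.can_have_indirect and not (d.is_na and c.is_na):
                        cell = f"{d} ({c})"
                    row[f.value] = cell
                rows.append(row)
            overall = by_id[inv.study_id].overall
            rows.append(
                {"study_id": inv.study_id, "row": "overall"}
                | {f.value: str(overall[f]) for f in MetadataField}
            )
        rows.append(
            {"study_id": "", "row": "median"}
            | {
                f.value: ("na" if self.medians[f] is None else f"{self.medians[f]:g}")
                for f in MetadataField
            }
        )
        return pd.DataFrame(rows, columns=["study_id", "row"] + [f.value for f in MetadataField])

    def status_table(self) -> pd.DataFrame:
        """Per-study derived (and, when known, reported) completeness status."""
        return pd.DataFrame(
            [
                {
                    "study_id": r.study_id,
                    "derived_status": r.status.value,
                    "reported_status": "" if r.reported_status is None else r.reported_status.value,
                    "discrepant": r.discrepant,
                }
                for r in self.results
            ]
        )

    def tally_line(self) -> str:
        return " ".join(
            f"{status.value}={self.status_tally[status]}"
            for status in (
                CompletenessStatus.COMPLETE_ALL,
                CompletenessStatus.COMPLETE_SOME,
                CompletenessStatus.PARTIAL,
                CompletenessStatus.MISSING,
            )
        )

    def to_json_dict(self) -> dict:
        return self.model_dump(mode="json")


def build_summary(
    invs: Sequence[StudyInventory], channel: Channel = Channel.DIRECT
) -> AssessmentReport:
    """Score, classify and summarise a set of study inventories."""
    results: list[StudyResult] = []
    warnings_: list[InventoryIssue] = []
    for inv in invs:
        overall = aggregate_overall(inv, channel)
        status = classify_study(overall)
        results.append(
            StudyResult(
                study_id=inv.study_id,
                overall=overall,
                status=status,
                reported_status=inv.reported_overall_status,
            )
        )
        warnings_.extend(validate_inventory(inv))
    tally = {status: 0 for status in CompletenessStatus}
    for r in results:
        tally[r.status] += 1
    discrepancies = [
        f"{r.study_id}: derived {r.status.value} != reported {r.reported_status.value}"
        for r in results
        if r.discrepant
    ]
    medians = (
        median_field_scores([r.overall for r in results])
        if results
        else {f: None for f in MetadataField}
    )
    return AssessmentReport(
        channel=channel,
        results=results,
        medians=medians,
        source_counts=count_source_availability(invs, channel),
        infrastructure_counts=summarize_infrastructure(invs),
        status_tally=tally,
        discrepancies=discrepancies,
        warnings=warnings_,
    )
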