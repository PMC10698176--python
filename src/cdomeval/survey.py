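"""FAIR-principles checklist survey: data model, validation, aggregation.

One principal investigator per study answered yes/no to a checklist derived
from the FAIR guiding principles (Findability, Accessibility,
Interoperability, Reusability), applied to their study's chronic disease
outcome metadata, and rated four potential barriers to FAIRness — limited
financial, human and technical resources, and limited incentives — as very
important / moderately important / not important.  Free-text barriers could
be added and rated the same way.

The default checklist instantiates the fifteen standard FAIR criteria
(F1-F4, A1, A1.1, A1.2, A2, I1-I3, R1, R1.1-R1.3).  Sub-criteria are
conditional: A1.1/A1.2 apply only when A1 was answered yes, R1.1-R1.3 only
when R1 was — a respondent with an unmet parent leaves them blank and drops
out of both numerator and denominator.  Elsewhere a blank counts as not-yes:
respondents were instructed to always answer yes or no, so a blank is a
deviation, not a skip.
"""

from __future__ import annotations

import csv
import enum
import json
import re
from pathlib import Path
from typing import Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FAIRCategory",
    "ChecklistItem",
    "default_checklist",
    "Answer",
    "BarrierRating",
    "BUILTIN_BARRIERS",
    "SurveyResponse",
    "SurveyIssue",
    "validate_response",
    "ItemSummary",
    "BarrierSummary",
    "SurveySummary",
    "aggregate_checklist",
    "aggregate_barriers",
    "normalize_barrier_name",
    "read_responses",
    "write_responses",
]


class FAIRCategory(str, enum.Enum):
    FINDABILITY = "findability"
    ACCESSIBILITY = "accessibility"
    INTEROPERABILITY = "interoperability"
    REUSABILITY = "reusability"


class ChecklistItem(BaseModel):
    """One FAIR criterion; ``parent`` marks conditional sub-criteria."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    text: str
    category: FAIRCategory
    parent: Optional[str] = None


_DEFAULT_ITEMS: tuple[tuple[str, str, FAIRCategory, Optional[str]], ...] = (
    ("F1", "(Meta)data are assigned a globally unique and persistent identifier", FAIRCategory.FINDABILITY, None),
    ("F2", "Data are described with rich metadata", FAIRCategory.FINDABILITY, None),
    ("F3", "Metadata clearly and explicitly include the identifier of the data they describe", FAIRCategory.FINDABILITY, None),
    ("F4", "(Meta)data are registered or indexed in a searchable resource", FAIRCategory.FINDABILITY, None),
    ("A1", "(Meta)data are retrievable by their identifier using a standardised communications protocol", FAIRCategory.ACCESSIBILITY, None),
    ("A1.1", "The protocol is open, free, and universally implementable", FAIRCategory.ACCESSIBILITY, "A1"),
    ("A1.2", "The protocol allows for an authentication and authorisation procedure, where necessary", FAIRCategory.ACCESSIBILITY, "A1"),
    ("A2", "Metadata are accessible, even when the data are no longer available", FAIRCategory.ACCESSIBILITY, None),
    ("I1", "(Meta)data use a formal, accessible, shared, and broadly applicable language for knowledge representation", FAIRCategory.INTEROPERABILITY, None),
    ("I2", "(Meta)data use vocabularies that follow FAIR principles", FAIRCategory.INTEROPERABILITY, None),
    ("I3", "(Meta)data include qualified references to other (meta)data", FAIRCategory.INTEROPERABILITY, None),
    ("R1", "(Meta)data are richly described with a plurality of accurate and relevant attributes", FAIRCategory.REUSABILITY, None),
    ("R1.1", "(Meta)data are released with a clear and accessible data usage license", FAIRCategory.REUSABILITY, "R1"),
    ("R1.2", "(Meta)data are associated with detailed provenance", FAIRCategory.REUSABILITY, "R1"),
    ("R1.3", "(Meta)data meet domain-relevant community standards", FAIRCategory.REUSABILITY, "R1"),
)


def default_checklist() -> list[ChecklistItem]:
    """The fifteen standard FAIR criteria; item texts are replaceable."""
    return [
        ChecklistItem(item_id=i, text=t, category=c, parent=p)
        for i, t, c, p in _DEFAULT_ITEMS
    ]


def _check_items(items: Sequence[ChecklistItem]) -> dict[str, ChecklistItem]:
    by_id: dict[str, ChecklistItem] = {}
    for item in items:
        if item.item_id in by_id:
            raise ValueError(f"duplicate checklist item {item.item_id}")
        by_id[item.item_id] = item
    for item in items:
        if item.parent is not None:
            parent = by_id.get(item.parent)
            if parent is None:
                raise ValueError(f"{item.item_id}: unknown parent {item.parent}")
            if parent.category is not item.category:
                raise ValueError(f"{item.item_id}: parent in different category")
            if parent.parent is not None:
                raise ValueError(f"{item.item_id}: nested conditional items unsupported")
    return by_id


class Answer(str, enum.Enum):
    YES = "yes"
    NO = "no"
    BLANK = "blank"


class BarrierRating(str, enum.Enum):
    VERY_IMPORTANT = "very_important"
    MODERATELY_IMPORTANT = "moderately_important"
    NOT_IMPORTANT = "not_important"


BUILTIN_BARRIERS = (
    "limited_financial",
    "limited_human",
    "limited_technical",
    "limited_incentives",
)


def normalize_barrier_name(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.strip().lower()).strip("_")


class SurveyResponse(BaseModel):
    """One principal investigator's completed checklist (one per study)."""

    respondent_id: str
    answers: dict[str, Answer] = Field(default_factory=dict)
    comments: dict[str, str] = Field(default_factory=dict)
    barriers: dict[str, BarrierRating]

    @model_validator(mode="after")
    def _builtin_barriers(self) -> "SurveyResponse":
        missing = [b for b in BUILTIN_BARRIERS if b not in self.barriers]
        if missing:
            raise ValueError(f"missing built-in barrier ratings: {', '.join(missing)}")
        return self

    def answer(self, item_id: str) -> Answer:
        return self.answers.get(item_id, Answer.BLANK)


class SurveyIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    respondent_id: str
    item_id: str
    message: str

    def __str__(self) -> str:
        return f"{self.respondent_id}/{self.item_id}: {self.message}"


def validate_response(
    resp: SurveyResponse, items: Optional[Sequence[ChecklistItem]] = None
) -> list[SurveyIssue]:
    """Flag unknown item ids and conditional items answered without a yes parent."""
    items = default_checklist() if items is None else list(items)
    by_id = _check_items(items)
    issues: list[SurveyIssue] = []
    for item_id in resp.answers:
        if item_id not in by_id:
            issues.append(
                SurveyIssue(
                    respondent_id=resp.respondent_id,
                    item_id=item_id,
                    message="unknown checklist item",
                )
            )
    for item in items:
        if item.parent is None:
            continue
        if resp.answer(item.item_id) is not Answer.BLANK and resp.answer(item.parent) is not Answer.YES:
            issues.append(
                SurveyIssue(
                    respondent_id=resp.respondent_id,
                    item_id=item.item_id,
                    message=f"answered although parent {item.parent} is not yes",
                )
            )
    return issues


class ItemSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    #: None marks an undefined percentage (denominator of size zero).
    percent_yes: Optional[float]
    denominator: int


class BarrierSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    percent_very_important: float
    percent_moderately_important: float
    percent_not_important: float


class SurveySummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_respondents: int
    items: dict[str, ItemSummary] = Field(default_factory=dict)
    barriers: dict[str, BarrierSummary] = Field(default_factory=dict)


def _pct(count: int, denom: int) -> float:
    return round(100.0 * count / denom, 1)


def aggregate_checklist(
    resps: Sequence[SurveyResponse],
    items: Optional[Sequence[ChecklistItem]] = None,
    conditional_denominator: str = "parent_yes",
) -> SurveySummary:
    """Percent-yes per checklist item.

    Unconditional items use all respondents as denominator, blanks counting
    as not-yes.  Conditional items, with the default
    ``conditional_denominator="parent_yes"``, use only respondents who
    answered yes to the parent (percent of applicable); pass ``"all"`` to
    divide by all respondents instead.  A zero denominator yields an
    undefined marker (``percent_yes=None``), not 0.
    """
    if not resps:
        raise ValueError("aggregate_checklist requires at least one response")
    if conditional_denominator not in {"parent_yes", "all"}:
        raise ValueError("conditional_denominator must be 'parent_yes' or 'all'")
    items = default_checklist() if items is None else list(items)
    _check_items(items)
    n = len(resps)
    summary: dict[str, ItemSummary] = {}
    for item in items:
        if item.parent is None or conditional_denominator == "all":
            pool = list(resps)
        else:
            pool = [r for r in resps if r.answer(item.parent) is Answer.YES]
        yes = sum(1 for r in pool if r.answer(item.item_id) is Answer.YES)
        summary[item.item_id] = ItemSummary(
            percent_yes=_pct(yes, len(pool)) if pool else None,
            denominator=len(pool),
        )
    return SurveySummary(n_respondents=n, items=summary)


def aggregate_barriers(resps: Sequence[SurveyResponse]) -> SurveySummary:
    """Percentage distribution over the three importance levels, per barrier.

    Built-in barriers are rated by every respondent, so their three
    percentages sum to 100 up to rounding (one decimal).  Free-text barriers
    are aggregated under their normalized name with the same all-respondents
    denominator; respondents who did not mention one contribute to no level.
    """
    if not resps:
        raise ValueError("aggregate_barriers requires at least one response")
    n = len(resps)
    names: list[str] = list(BUILTIN_BARRIERS)
    for r in resps:
        for raw in r.barriers:
            name = normalize_barrier_name(raw)
            if name not in names:
                names.append(name)
    barriers: dict[str, BarrierSummary] = {}
    for name in names:
        counts = {level: 0 for level in BarrierRating}
        for r in resps:
            for raw, rating in r.barriers.items():
                if normalize_barrier_name(raw) == name:
                    counts[rating] += 1
        barriers[name] = BarrierSummary(
            percent_very_important=_pct(counts[BarrierRating.VERY_IMPORTANT], n),
            percent_moderately_important=_pct(counts[BarrierRating.MODERATELY_IMPORTANT], n),
            percent_not_important=_pct(counts[BarrierRating.NOT_IMPORTANT], n),
        )
    return SurveySummary(n_respondents=n, barriers=barriers)


# ---------------------------------------------------------------------------
# Response IO (CSV: one row per respondent; JSON: structured document)
# ---------------------------------------------------------------------------

_BARRIER_PREFIX = "barrier:"
_COMMENT_PREFIX = "comment:"


def write_responses(
    resps: Sequence[SurveyResponse],
    path: Union[str, Path],
    format: str = "csv",
    items: Optional[Sequence[ChecklistItem]] = None,
) -> None:
    path = Path(path)
    if format == "structured":
        doc = {"responses": [r.model_dump(mode="json") for r in resps]}
        path.write_text(json.dumps(doc, indent=1, ensure_ascii=False) + "\n", "utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    items = default_checklist() if items is None else list(items)
    item_ids = [i.item_id for i in items]
    barrier_names: list[str] = list(BUILTIN_BARRIERS)
    comment_ids: list[str] = []
    for r in resps:
        for raw in r.barriers:
            name = normalize_barrier_name(raw)
            if name not in barrier_names:
                barrier_names.append(name)
        for item_id in r.comments:
            if item_id not in comment_ids:
                comment_ids.append(item_id)
    header = (
        ["respondent_id"]
        + item_ids
        + [_BARRIER_PREFIX + b for b in barrier_names]
        + [_COMMENT_PREFIX + c for c in comment_ids]
    )
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for r in resps:
            normalized = {normalize_barrier_name(k): v for k, v in r.barriers.items()}
            row = [r.respondent_id]
            row += [
                "" if r.answer(i) is Answer.BLANK else r.answer(i).value for i in item_ids
            ]
            row += [
                normalized[b].value if b in normalized else "" for b in barrier_names
            ]
            row += [r.comments.get(c, "") for c in comment_ids]
            writer.writerow(row)


def read_responses(path: Union[str, Path], format: str = "csv") -> list[SurveyResponse]:
    path = Path(path)
    if format == "structured":
        doc = json.loads(path.read_text("utf-8"))
        return [SurveyResponse.model_validate(r) for r in doc["responses"]]
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    out: list[SurveyResponse] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "respondent_id" not in reader.fieldnames:
            raise ValueError(f"{path.name}: missing respondent_id column")
        for row in reader:
            answers: dict[str, Answer] = {}
            barriers: dict[str, BarrierRating] = {}
            comments: dict[str, str] = {}
            for col, cell in row.items():
                if col == "respondent_id" or cell is None:
                    continue
                cell = cell.strip()
                if col.startswith(_BARRIER_PREFIX):
                    if cell:
                        barriers[col[len(_BARRIER_PREFIX):]] = BarrierRating(cell)
                elif col.startswith(_COMMENT_PREFIX):
                    if cell:
                        comments[col[len(_COMMENT_PREFIX):]] = cell
                elif cell:
                    answers[col] = Answer(cell)
            out.append(
                SurveyResponse(
                    respondent_id=row["respondent_id"],
                    answers=answers,
                    comments=comments,
                    barriers=barriers,
                )
            )
    return out
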