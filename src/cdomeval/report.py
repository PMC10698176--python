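"""Rendering of assessment reports as CSV, JSON and markdown tables.

Output ordering is fixed — studies in input order, fields in canonical
order — so that repeated runs are diff-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .inventory import StudyInventory
from .scoring import AssessmentReport
from .survey import SurveySummary

__all__ = [
    "markdown_table",
    "write_report",
    "survey_summary_frames",
    "write_survey_summary",
]


def markdown_table(df: pd.DataFrame) -> str:
    """Render a DataFrame as a GitHub-flavoured markdown table."""
    cols = [str(c) for c in df.columns]
    body = [[("" if pd.isna(v) else str(v)) for v in row] for row in df.itertuples(index=False)]
    widths = [
        max(len(cols[j]), *(len(r[j]) for r in body)) if body else len(cols[j])
        for j in range(len(cols))
    ]

    def line(cells: Sequence[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"

    out = [line(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    out += [line(r) for r in body]
    return "\n".join(out) + "\n"


def _write_frame(df: pd.DataFrame, path: Path, format: str) -> None:
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "markdown":
        path.write_text(markdown_table(df), "utf-8")
    else:
        raise ValueError(f"unknown table format {format!r}")


def write_report(
    report: AssessmentReport,
    invs: Sequence[StudyInventory],
    out_dir: Path,
    formats: Sequence[str] = ("csv", "json"),
) -> list[Path]:
    """Write the status table, score matrix, counts and issue log to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    status = report.status_table()
    matrix = report.score_matrix(invs)
    counts = pd.DataFrame(
        [{"source": s.value, "n_studies": n} for s, n in report.source_counts.items()]
    )
    infra = pd.DataFrame(
        [{"category": k, "n_studies": v} for k, v in report.infrastructure_counts.items()]
    )
    for format in formats:
        if format == "json":
            path = out_dir / "report.json"
            path.write_text(
                json.dumps(report.to_json_dict(), indent=1, ensure_ascii=False) + "\n", "utf-8"
            )
            written.append(path)
            continue
        ext = "md" if format == "markdown" else "csv"
        for name, df in (
            ("status_table", status),
            ("score_matrix", matrix),
            ("source_counts", counts),
            ("infrastructure_counts", infra),
        ):
            path = out_dir / f"{name}.{ext}"
            _write_frame(df, path, format)
            written.append(path)
    issues = out_dir / "issues.jsonl"
    with issues.open("w", encoding="utf-8") as fh:
        for w in report.warnings:
            fh.write(json.dumps(w.model_dump(mode="json")) + "\n")
    written.append(issues)
    return written


def survey_summary_frames(summary: SurveySummary) -> dict[str, pd.DataFrame]:
    items = pd.DataFrame(
        [
            {
                "item_id": item_id,
                "percent_yes": "" if s.percent_yes is None else s.percent_yes,
                "denominator": s.denominator,
            }
            for item_id, s in summary.items.items()
        ]
    )
    barriers = pd.DataFrame(
        [
            {
                "barrier": name,
                "very_important": b.percent_very_important,
                "moderately_important": b.percent_moderately_important,
                "not_important": b.percent_not_important,
            }
            for name, b in summary.barriers.items()
        ]
    )
    return {"checklist_summary": items, "barrier_summary": barriers}


def write_survey_summary(
    summary: SurveySummary, out_dir: Path, formats: Sequence[str] = ("csv", "json")
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    frames = survey_summary_frames(summary)
    for format in formats:
        if format == "json":
            path = out_dir / "survey_summary.json"
            path.write_text(
                json.dumps(summary.model_dump(mode="json"), indent=1) + "\n", "utf-8"
            )
            written.append(path)
            continue
        ext = "md" if format == "markdown" else "csv"
        for name, df in frames.items():
            if df.empty:
                continue
            path = out_dir / f"{name}.{ext}"
            _write_frame(df, path, format)
            written.append(path)
    return written
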