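"""Reading and writing the pipeline's tabular text formats.

Three delimited-text tables describe a cohort:

* ``units`` — long format, one row per subject x task x unit with the
  unit correctness score and overlap counts;
* ``screening`` — one row per subject with the four screening-test
  results;
* ``subjects`` — one row per subject with group label and demographics.

Validation is strict: malformed rows are reported with their line
number in the source file.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .scoring import (
    DEFAULT_PARTITION,
    UnitPartition,
    UnitScore,
    ValidationError,
    summarize_task,
)
from .screening import ScreeningCutoffs, ScreeningResult
from .simulate import SubjectRecord

UNIT_COLUMNS = [
    "subject_id",
    "task",
    "unit_id",
    "correctness",
    "complete_overlaps",
    "incomplete_overlaps",
]
SCREENING_COLUMNS = [
    "subject_id",
    "line_cancel_left_omissions",
    "line_cancel_right_omissions",
    "star_cancel_score",
    "line_bisection_deviation",
    "landscape_left_details_omitted",
]
SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education_years",
    "mmse",
    "weeks_since_onset",
    "diagnosis",
]
SUMMARY_COLUMNS = [
    "subject_id",
    "task",
    "total_score",
    "left_score",
    "right_score",
    "laterality_index",
    "left_overlap",
    "right_overlap",
    "total_overlap",
]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return frame


def read_unit_scores(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format unit-score table."""
    frame = _read_table(path, UNIT_COLUMNS)
    errors: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            UnitScore(
                unit_id=int(row["unit_id"]),
                correctness=float(row["correctness"]),
                complete_overlaps=int(row["complete_overlaps"]),
                incomplete_overlaps=int(row["incomplete_overlaps"]),
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
        if row["task"] not in ("copying", "tracing"):
            errors.append(f"line {line}: task must be 'copying' or 'tracing'")
        if len(errors) >= 10:
            errors.append("... further errors suppressed")
            break
    if errors:
        raise ValidationError(f"{path}:\n" + "\n".join(errors))
    return frame


def units_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], list[UnitScore]]:
    """Group a validated unit table into UnitScore lists per subject/task."""
    grouped: dict[tuple[str, str], list[UnitScore]] = {}
    for (subject, task), sub in frame.groupby(["subject_id", "task"], sort=True):
        grouped[(str(subject), str(task))] = [
            UnitScore(
                unit_id=int(r.unit_id),
                correctness=float(r.correctness),
                complete_overlaps=int(r.complete_overlaps),
                incomplete_overlaps=int(r.incomplete_overlaps),
            )
            for r in sub.itertuples()
        ]
    return grouped


def summarize_subjects(
    units: pd.DataFrame, partition: UnitPartition = DEFAULT_PARTITION
) -> pd.DataFrame:
    """Per-subject, per-task derived totals (fixed column order)."""
    rows = []
    for (subject, task), unit_list in units_from_frame(units).items():
        summary = summarize_task(unit_list, partition, task=task)
        rows.append({"subject_id": subject, **summary.as_dict()})
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return frame.sort_values(["subject_id", "task"], kind="stable").reset_index(drop=True)


def read_screening(path: str | Path) -> pd.DataFrame:
    frame = _read_table(path, SCREENING_COLUMNS)
    errors = []
    for idx, row in frame.iterrows():
        try:
            screening_result_from_row(row)
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise ValidationError(f"{path}:\n" + "\n".join(errors[:10]))
    return frame


def screening_result_from_row(row: Mapping) -> ScreeningResult:
    return ScreeningResult(
        line_cancel_left_omissions=int(row["line_cancel_left_omissions"]),
        line_cancel_right_omissions=int(row["line_cancel_right_omissions"]),
        star_cancel_score=int(row["star_cancel_score"]),
        line_bisection_deviation=float(row["line_bisection_deviation"]),
        landscape_left_details_omitted=int(row["landscape_left_details_omitted"]),
    )


def read_subjects(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ["subject_id", "group"])


def cohort_to_frames(cohort: Iterable[SubjectRecord]) -> dict[str, pd.DataFrame]:
    """Flatten a generated cohort into the three standard tables."""
    unit_rows, screening_rows, subject_rows = [], [], []
    for s in cohort:
        subject_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "sex": s.sex,
                "education_years": s.education_years,
                "mmse": s.mmse,
                "weeks_since_onset": s.weeks_since_onset,
                "diagnosis": s.diagnosis,
            }
        )
        screening_rows.append(
            {
                "subject_id": s.subject_id,
                "line_cancel_left_omissions": s.screening.line_cancel_left_omissions,
                "line_cancel_right_omissions": s.screening.line_cancel_right_omissions,
                "star_cancel_score": s.screening.star_cancel_score,
                "line_bisection_deviation": s.screening.line_bisection_deviation,
                "landscape_left_details_omitted": s.screening.landscape_left_details_omitted,
            }
        )
        for task, units in s.units.items():
            for u in units:
                unit_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "task": task,
                        "unit_id": u.unit_id,
                        "correctness": u.correctness,
                        "complete_overlaps": u.complete_overlaps,
                        "incomplete_overlaps": u.incomplete_overlaps,
                    }
                )
    return {
        "units": pd.DataFrame(unit_rows, columns=UNIT_COLUMNS),
        "screening": pd.DataFrame(screening_rows, columns=SCREENING_COLUMNS),
        "subjects": pd.DataFrame(subject_rows, columns=SUBJECT_COLUMNS),
    }


def write_cohort(cohort: Iterable[SubjectRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the three cohort tables as CSV; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(cohort)
    paths = {}
    for name, frame in frames.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def load_partition(path: str | Path) -> UnitPartition:
    """Load a left/right/unassigned unit partition from YAML or JSON."""
    path = Path(path)
    with open(path) as handle:
        data = json.load(handle) if path.suffix == ".json" else yaml.safe_load(handle)
    try:
        return UnitPartition(
            left_units=frozenset(data["left"]),
            right_units=frozenset(data["right"]),
            unassigned_units=frozenset(data.get("unassigned", [])),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing partition key {exc}") from exc


def load_cutoffs(path: str | Path) -> ScreeningCutoffs:
    """Load screening cutoffs from YAML or JSON."""
    path = Path(path)
    with open(path) as handle:
        data = json.load(handle) if path.suffix == ".json" else yaml.safe_load(handle)
    return ScreeningCutoffs(**data)
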