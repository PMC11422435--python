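"""Unit-level scoring of complex-figure copy and trace performances.

The Rey-Osterrieth complex figure is scored over 18 structural units,
each rated 0, 0.5, 1, 1.5 or 2 points for accuracy and placement
(36 points maximum).  To quantify lateralised performance the units are
split into a left-sided set (maximum 12 points), a right-sided set
(maximum 16 points) and midline units assigned to neither side.  The
Laterality Index

    LI = (left score / 12) / (right score / 16)

is below 1 when the right-sided structures are reproduced proportionally
better than the left-sided ones, the typical pattern in left-sided
spatial neglect.

Re-trace ("overlapping") events are scored per unit: 1 point for a
complete overlap, 0.5 points for an incomplete overlap; left, right and
total overlapping scores sum these unit points over the respective unit
sets (the total includes midline units).

All score arithmetic is carried out in integer half-points internally
and converted to decimal points on output, so sums are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Iterable

__all__ = [
    "ALLOWED_CORRECTNESS",
    "DEFAULT_PARTITION",
    "N_UNITS",
    "ConfigurationError",
    "TaskSummary",
    "UnitPartition",
    "UnitScore",
    "ValidationError",
    "lateral_scores",
    "laterality_index",
    "overlap_scores",
    "summarize_task",
    "total_score",
]

N_UNITS = 18
ALLOWED_CORRECTNESS = (0.0, 0.5, 1.0, 1.5, 2.0)
LEFT_MAX = 12.0
RIGHT_MAX = 16.0


class ValidationError(ValueError):
    """Invalid input data (scores, counts, missing or duplicate units)."""


class ConfigurationError(ValueError):
    """Invalid configuration (e.g. a unit partition with wrong maxima)."""


def _check_half_points(value: float, name: str) -> int:
    """Convert ``value`` (in points) to integer half-points, or raise."""
    doubled = 2.0 * float(value)
    if not math.isfinite(doubled) or abs(doubled - round(doubled)) > 1e-9:
        raise ValidationError(f"{name} must be a multiple of 0.5, got {value!r}")
    return int(round(doubled))


@dataclass(frozen=True)
class UnitScore:
    """Score sheet entry for one structural unit of one performance.

    Parameters
    ----------
    unit_id
        Unit number, 1-18.
    correctness
        Accuracy/placement score, one of {0, 0.5, 1, 1.5, 2}.
    complete_overlaps, incomplete_overlaps
        Number of times the unit was re-traced completely / partially.
    """

    unit_id: int
    correctness: float
    complete_overlaps: int = 0
    incomplete_overlaps: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.unit_id, int) or not 1 <= self.unit_id <= N_UNITS:
            raise ValidationError(
                f"unit_id must be an integer in 1..{N_UNITS}, got {self.unit_id!r}"
            )
        if float(self.correctness) not in ALLOWED_CORRECTNESS:
            raise ValidationError(
                f"unit {self.unit_id}: correctness must be one of "
                f"{ALLOWED_CORRECTNESS}, got {self.correctness!r}"
            )
        for name in ("complete_overlaps", "incomplete_overlaps"):
            count = getattr(self, name)
            if not isinstance(count, int) or isinstance(count, bool) or count < 0:
                raise ValidationError(
                    f"unit {self.unit_id}: {name} must be a non-negative "
                    f"integer, got {count!r}"
                )

    @property
    def overlap_points(self) -> float:
        """Overlap points for this unit: 1 per complete, 0.5 per incomplete."""
        return self.complete_overlaps + 0.5 * self.incomplete_overlaps


@dataclass(frozen=True)
class UnitPartition:
    """Assignment of the 18 scoring units to left, right and midline sets.

    The left set must carry a 12-point maximum (6 units) and the right
    set a 16-point maximum (8 units); the remaining units are midline
    and contribute to neither lateral score.
    """

    left_units: frozenset[int]
    right_units: frozenset[int]
    unassigned_units: frozenset[int]

    def __post_init__(self) -> None:
        left = frozenset(self.left_units)
        right = frozenset(self.right_units)
        mid = frozenset(self.unassigned_units)
        object.__setattr__(self, "left_units", left)
        object.__setattr__(self, "right_units", right)
        object.__setattr__(self, "unassigned_units", mid)
        all_ids = frozenset(range(1, N_UNITS + 1))
        if left | right | mid != all_ids or len(left) + len(right) + len(mid) != N_UNITS:
            raise ConfigurationError(
                "partition sets must be disjoint and cover units 1..18; got "
                f"left={sorted(left)}, right={sorted(right)}, unassigned={sorted(mid)}"
            )
        if 2 * len(left) != LEFT_MAX or 2 * len(right) != RIGHT_MAX:
            raise ConfigurationError(
                "partition maxima must be 12 (left) and 16 (right) points; got "
                f"{2 * len(left)} and {2 * len(right)}"
            )


#: Default left/right assignment.  The published figure marks the sides
#: graphically without listing unit numbers, so this concrete set is a
#: documented, overridable default consistent with the standard
#: Osterrieth unit layout and the required (12, 16) maxima: the
#: upper-left cross (1), left small rectangle and its details (6-8) and
#: the lower-left elements (17, 18) are left-sided; the right-attached
#: triangle complex and right-field details (9-16) are right-sided; the
#: large rectangle and its diagonals/medians (2-5) are midline.
DEFAULT_PARTITION = UnitPartition(
    left_units=frozenset({1, 6, 7, 8, 17, 18}),
    right_units=frozenset({9, 10, 11, 12, 13, 14, 15, 16}),
    unassigned_units=frozenset({2, 3, 4, 5}),
)


def _by_unit_id(units: Iterable[UnitScore]) -> dict[int, UnitScore]:
    """Index units by id, requiring exactly one entry per unit 1..18."""
    seen: dict[int, UnitScore] = {}
    duplicates: list[int] = []
    for unit in units:
        if unit.unit_id in seen:
            duplicates.append(unit.unit_id)
        seen[unit.unit_id] = unit
    missing = sorted(set(range(1, N_UNITS + 1)) - set(seen))
    if duplicates or missing:
        parts = []
        if missing:
            parts.append(f"missing unit ids {missing}")
        if duplicates:
            parts.append(f"duplicate unit ids {sorted(set(duplicates))}")
        raise ValidationError("; ".join(parts))
    return seen


def total_score(units: Collection[UnitScore]) -> float:
    """Conventional 36-point figure score: sum of unit correctness values."""
    indexed = _by_unit_id(units)
    half = sum(_check_half_points(u.correctness, "correctness") for u in indexed.values())
    return half / 2.0


def lateral_scores(
    units: Collection[UnitScore], partition: UnitPartition = DEFAULT_PARTITION
) -> tuple[float, float]:
    """Left (max 12) and right (max 16) construction scores.

    Midline units contribute to neither side.
    """
    indexed = _by_unit_id(units)
    left_half = sum(
        _check_half_points(indexed[i].correctness, "correctness")
        for i in partition.left_units
    )
    right_half = sum(
        _check_half_points(indexed[i].correctness, "correctness")
        for i in partition.right_units
    )
    return left_half / 2.0, right_half / 2.0


def laterality_index(left: float, right: float) -> float:
    """Laterality Index LI = (left / 12) / (right / 16).

    LI < 1 indicates a greater proportion of correct responses in the
    right-sided structures (the left-neglect direction); LI > 1 the
    opposite.  When the right score is zero the ratio is undefined and
    NaN is returned (downstream statistics exclude such values with a
    logged count).
    """
    if not (0.0 <= float(left) <= LEFT_MAX):
        raise ValidationError(f"left score must be in [0, {LEFT_MAX}], got {left!r}")
    if not (0.0 <= float(right) <= RIGHT_MAX):
        raise ValidationError(f"right score must be in [0, {RIGHT_MAX}], got {right!r}")
    if right == 0:
        return math.nan
    return (left / LEFT_MAX) / (right / RIGHT_MAX)


def overlap_scores(
    units: Collection[UnitScore], partition: UnitPartition = DEFAULT_PARTITION
) -> tuple[float, float, float]:
    """Left, right and total overlapping scores.

    Per-unit overlap points are 1 per complete re-trace and 0.5 per
    incomplete re-trace.  The total sums over all 18 units, so midline
    units count toward the total but toward neither side.
    """
    indexed = _by_unit_id(units)
    left_half = sum(
        _check_half_points(indexed[i].overlap_points, "overlap points")
        for i in partition.left_units
    )
    right_half = sum(
        _check_half_points(indexed[i].overlap_points, "overlap points")
        for i in partition.right_units
    )
    total_half = sum(
        _check_half_points(u.overlap_points, "overlap points") for u in indexed.values()
    )
    return left_half / 2.0, right_half / 2.0, total_half / 2.0


@dataclass(frozen=True)
class TaskSummary:
    """Derived per-performance totals for one task (copying or tracing)."""

    task: str
    total_score: float
    left_score: float
    right_score: float
    laterality_index: float  # NaN when undefined (right score 0)
    left_overlap: float
    right_overlap: float
    total_overlap: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "task": self.task,
            "total_score": self.total_score,
            "left_score": self.left_score,
            "right_score": self.right_score,
            "laterality_index": self.laterality_index,
            "left_overlap": self.left_overlap,
            "right_overlap": self.right_overlap,
            "total_overlap": self.total_overlap,
        }


def summarize_task(
    units: Collection[UnitScore],
    partition: UnitPartition = DEFAULT_PARTITION,
    task: str = "copying",
) -> TaskSummary:
    """Compute all derived totals for one scored performance."""
    if task not in ("copying", "tracing"):
        raise ValidationError(f"task must be 'copying' or 'tracing', got {task!r}")
    total = total_score(units)
    left, right = lateral_scores(units, partition)
    li = laterality_index(left, right)
    ol_left, ol_right, ol_total = overlap_scores(units, partition)
    return TaskSummary(
        task=task,
        total_score=total,
        left_score=left,
        right_score=right,
        laterality_index=li,
        left_overlap=ol_left,
        right_overlap=ol_right,
        total_overlap=ol_total,
    )
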