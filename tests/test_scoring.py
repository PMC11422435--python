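"""Unit-level figure scoring: totals, lateral scores, LI, overlaps."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rocftrace.scoring import (
    DEFAULT_PARTITION,
    ConfigurationError,
    UnitPartition,
    UnitScore,
    ValidationError,
    lateral_scores,
    laterality_index,
    overlap_scores,
    summarize_task,
    total_score,
)
from tests.conftest import build_units

LEFT = sorted(DEFAULT_PARTITION.left_units)
RIGHT = sorted(DEFAULT_PARTITION.right_units)
MID = sorted(DEFAULT_PARTITION.unassigned_units)

correctness_values = st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0])
unit_sheet = st.lists(correctness_values, min_size=18, max_size=18).map(
    lambda vals: build_units(dict(zip(range(1, 19), vals)))
)


class TestTotalScore:
    @pytest.mark.parametrize(
        "correctness, expected",
        [
            (2.0, 36.0),  # flawless figure hits the 36-point maximum
            (0.0, 0.0),
            ({1: 1.5, 2: 0.5}, 34.0),  # 16 units at 2 plus 1.5 + 0.5
        ],
    )
    def test_examples(self, correctness, expected):
        assert total_score(build_units(correctness)) == expected

    def test_missing_and_duplicate_units_are_named(self):
        units = build_units(2.0)
        with pytest.raises(ValidationError, match=r"missing unit ids \[18\]"):
            total_score(units[:-1])
        with pytest.raises(ValidationError, match=r"duplicate unit ids \[1\]"):
            total_score(units + [units[0]])

    def test_invalid_correctness_rejected(self):
        with pytest.raises(ValidationError, match="correctness"):
            UnitScore(unit_id=1, correctness=0.75)
        with pytest.raises(ValidationError, match="non-negative"):
            UnitScore(unit_id=1, correctness=2.0, complete_overlaps=-1)


class TestLateralScores:
    @pytest.mark.parametrize(
        "correctness, expected",
        [(2.0, (12.0, 16.0)), (0.0, (0.0, 0.0)), (1.0, (6.0, 8.0))],
    )
    def test_examples(self, correctness, expected):
        assert lateral_scores(build_units(correctness)) == expected

    def test_partition_with_wrong_maxima_rejected(self):
        with pytest.raises(ConfigurationError, match="maxima"):
            UnitPartition(
                left_units=frozenset(range(1, 8)),  # 7 units -> 14-point max
                right_units=frozenset(range(8, 16)),
                unassigned_units=frozenset(range(16, 19)),
            )

    def test_partition_must_cover_all_units(self):
        with pytest.raises(ConfigurationError, match="cover"):
            UnitPartition(
                left_units=frozenset({1, 2, 3, 4, 5, 6}),
                right_units=frozenset({7, 8, 9, 10, 11, 12, 13, 14}),
                unassigned_units=frozenset({15, 16, 17}),  # unit 18 missing
            )


class TestLateralityIndex:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            (12.0, 16.0, 1.0),
            (10.0, 16.0, 10.0 / 12.0),  # the 0.83 worked-example value
            (6.0, 8.0, 1.0),  # equal proportions
        ],
    )
    def test_examples(self, left, right, expected):
        assert laterality_index(left, right) == pytest.approx(expected)

    def test_undefined_when_right_zero(self):
        assert math.isnan(laterality_index(5.0, 0.0))
        assert math.isnan(laterality_index(0.0, 0.0))

    @pytest.mark.parametrize("left, right", [(-1, 8), (13, 8), (6, 17), (6, -0.5)])
    def test_out_of_range_rejected(self, left, right):
        with pytest.raises(ValidationError):
            laterality_index(left, right)

    def test_exhaustive_half_point_grid_matches_formula(self):
        """LI equals (left/12)/(right/16) on every attainable score pair."""
        for left2 in range(25):  # half-points 0..24
            for right2 in range(33):
                left, right = left2 / 2.0, right2 / 2.0
                li = laterality_index(left, right)
                if right == 0:
                    assert math.isnan(li)
                else:
                    assert li == pytest.approx((left / 12.0) / (right / 16.0), abs=1e-12)

    def test_scale_invariance(self):
        """Proportional score pairs give identical LI."""
        base = laterality_index(3.0, 4.0)
        assert laterality_index(6.0, 8.0) == pytest.approx(base)
        assert laterality_index(12.0, 16.0) == pytest.approx(base)


class TestOverlapScores:
    def test_worked_example_sides_and_total(self):
        units = build_units(2.0, overlaps={LEFT[0]: (1, 0), RIGHT[0]: (1, 1)})
        assert overlap_scores(units) == (1.0, 1.5, 2.5)

    def test_no_overlaps(self):
        assert overlap_scores(build_units(2.0)) == (0.0, 0.0, 0.0)

    def test_unassigned_unit_counts_toward_total_only(self):
        units = build_units(2.0, overlaps={MID[0]: (1, 0)})
        assert overlap_scores(units) == (0.0, 0.0, 1.0)


class TestSummarize:
    def test_perfect_figure(self, perfect_units):
        summary = summarize_task(perfect_units, task="copying")
        assert summary.total_score == 36.0
        assert (summary.left_score, summary.right_score) == (12.0, 16.0)
        assert summary.laterality_index == pytest.approx(1.0)
        assert summary.total_overlap == 0.0

    def test_worked_example_patient(self, worked_example_units):
        """Published single-patient example: copying 32 pts / LI 0.83,
        tracing 24 pts / LI 0.72, tracing overlaps 1.0 + 1.5 = 2.5."""
        copying = summarize_task(worked_example_units["copying"], task="copying")
        tracing = summarize_task(worked_example_units["tracing"], task="tracing")
        assert copying.total_score == 32.0
        assert round(copying.laterality_index, 2) == 0.83
        assert copying.total_overlap == 0.0
        assert tracing.total_score == 24.0
        assert round(tracing.laterality_index, 2) == 0.72
        assert (tracing.left_overlap, tracing.right_overlap) == (1.0, 1.5)
        assert tracing.total_overlap == 2.5

    def test_unknown_task_rejected(self, perfect_units):
        with pytest.raises(ValidationError, match="task"):
            summarize_task(perfect_units, task="recall")


class TestInvariants:
    @settings(max_examples=100, deadline=None)
    @given(unit_sheet)
    def test_additivity_and_permutation_invariance(self, units):
        total = total_score(units)
        left, right = lateral_scores(units)
        mid = sum(u.correctness for u in units if u.unit_id in DEFAULT_PARTITION.unassigned_units)
        assert total == pytest.approx(left + right + mid)
        shuffled = list(reversed(units))
        assert total_score(shuffled) == total
        assert lateral_scores(shuffled) == (left, right)

    @settings(max_examples=60, deadline=None)
    @given(unit_sheet, st.sampled_from(LEFT), st.sampled_from(RIGHT))
    def test_li_monotonicity(self, units, left_uid, right_uid):
        """Raising a left unit weakly raises LI; a right unit weakly lowers it."""
        def bump(uid):
            return [
                UnitScore(u.unit_id, min(2.0, u.correctness + 0.5))
                if u.unit_id == uid
                else u
                for u in units
            ]

        base = summarize_task(units).laterality_index
        up_left = summarize_task(bump(left_uid)).laterality_index
        up_right = summarize_task(bump(right_uid)).laterality_index
        if not math.isnan(base):
            assert up_left >= base - 1e-12
            if not math.isnan(up_right):
                assert up_right <= base + 1e-12

    @settings(max_examples=60, deadline=None)
    @given(
        st.dictionaries(
            st.integers(1, 18),
            st.tuples(st.integers(0, 3), st.integers(0, 3)),
            max_size=18,
        )
    )
    def test_overlap_decomposition(self, overlap_map):
        units = build_units(2.0, overlaps=overlap_map)
        left, right, total = overlap_scores(units)
        mid_points = sum(
            c + 0.5 * i
            for uid, (c, i) in overlap_map.items()
            if uid in DEFAULT_PARTITION.unassigned_units
        )
        assert total == pytest.approx(left + right + mid_points)
        if mid_points == 0:
            assert total == pytest.approx(left + right)
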