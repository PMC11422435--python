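"""Shared fixtures: hand-built unit score sheets and small cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from rocftrace.scoring import DEFAULT_PARTITION, UnitScore

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


def build_units(
    correctness: dict[int, float] | float = 2.0,
    overlaps: dict[int, tuple[int, int]] | None = None,
) -> list[UnitScore]:
    """All 18 units with the given per-unit correctness and overlaps.

    ``correctness`` may be a constant or a per-unit override mapping;
    ``overlaps`` maps unit id to (complete, incomplete) counts.
    """
    overlaps = overlaps or {}
    units = []
    for uid in range(1, 19):
        if isinstance(correctness, dict):
            c = correctness.get(uid, 2.0)
        else:
            c = correctness
        comp, inc = overlaps.get(uid, (0, 0))
        units.append(
            UnitScore(
                unit_id=uid,
                correctness=c,
                complete_overlaps=comp,
                incomplete_overlaps=inc,
            )
        )
    return units


@pytest.fixture
def perfect_units() -> list[UnitScore]:
    return build_units(2.0)


@pytest.fixture
def partition():
    return DEFAULT_PARTITION


@pytest.fixture
def worked_example_units() -> dict[str, list[UnitScore]]:
    """Single-patient score sheet reproducing a published worked example.

    Copying: 32 points total, left 10 / right 16 (LI 10/12 = 0.83), no
    overlaps.  Tracing: 24 points total, left 7 / right 13 (LI = 0.72
    to two decimals), overlapping scores left 1.0, right 1.5, total 2.5.
    """
    left = sorted(DEFAULT_PARTITION.left_units)  # [1, 6, 7, 8, 17, 18]
    right = sorted(DEFAULT_PARTITION.right_units)  # [9..16]
    mid = sorted(DEFAULT_PARTITION.unassigned_units)  # [2, 3, 4, 5]

    copying = {
        **dict(zip(left, [2.0, 2.0, 2.0, 2.0, 1.0, 1.0])),  # left sum 10
        **dict(zip(right, [2.0] * 8)),  # right sum 16
        **dict(zip(mid, [2.0, 2.0, 1.0, 1.0])),  # midline sum 6
    }
    tracing = {
        **dict(zip(left, [2.0, 2.0, 1.0, 1.0, 1.0, 0.0])),  # left sum 7
        **dict(zip(right, [2.0, 2.0, 2.0, 2.0, 2.0, 1.5, 1.0, 0.5])),  # right sum 13
        **dict(zip(mid, [2.0, 1.0, 1.0, 0.0])),  # midline sum 4
    }
    # tracing re-traces: one complete overlap on a left unit (1 point),
    # one complete plus one incomplete on right units (1.5 points)
    tracing_overlaps = {6: (1, 0), 13: (1, 0), 12: (0, 1)}
    return {
        "copying": build_units(copying),
        "tracing": build_units(tracing, overlaps=tracing_overlaps),
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced calibrated cohort shared by the slower integration tests."""
    from rocftrace.simulate import default_config, generate_cohort

    config = default_config({"healthy": 12, "usn_minus": 8, "usn_plus": 8})
    return generate_cohort(config, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
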