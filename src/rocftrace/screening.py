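"""Four-test screening battery for unilateral spatial neglect (USN).

Right-brain-damaged patients are classified USN+ if *any* of four
conventional screening tests shows a neglect-typical result:

* line cancellation — two or more omissions on the left half of the
  sheet in excess of the right-half omissions;
* star cancellation — cancelled-target count below the battery cutoff;
* line bisection — rightward deviation at or beyond the battery cutoff;
* landscape copying — omission of at least one of the five left-side
  details.

The star-cancellation and line-bisection cutoffs come from the
Behavioural Inattention Test (Japanese standardisation); the source
study cites the instrument without printing the numbers, so the values
shipped here are documented defaults that deployments should confirm
against their battery version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scoring import ValidationError

__all__ = [
    "DEFAULT_CUTOFFS",
    "ScreeningClassification",
    "ScreeningCutoffs",
    "ScreeningResult",
    "classify_usn",
]

USN_PLUS = "usn_plus"
USN_MINUS = "usn_minus"

LANDSCAPE_DETAILS = 5  # the landscape model contains five left-side objects


@dataclass(frozen=True)
class ScreeningResult:
    """One patient's raw results on the four screening tests.

    ``line_bisection_deviation`` is a signed deviation of the marked
    midpoint, positive toward the right (the left-neglect direction);
    its unit (percent of line length or mm) is declared in the cutoff
    configuration and must match the cutoff's unit.
    """

    line_cancel_left_omissions: int
    line_cancel_right_omissions: int
    star_cancel_score: int
    line_bisection_deviation: float
    landscape_left_details_omitted: int

    def __post_init__(self) -> None:
        for name in (
            "line_cancel_left_omissions",
            "line_cancel_right_omissions",
            "star_cancel_score",
            "landscape_left_details_omitted",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
        if self.landscape_left_details_omitted > LANDSCAPE_DETAILS:
            raise ValidationError(
                f"landscape_left_details_omitted must be <= {LANDSCAPE_DETAILS}, "
                f"got {self.landscape_left_details_omitted}"
            )


@dataclass(frozen=True)
class ScreeningCutoffs:
    """Decision thresholds for the four screening tests.

    star_cancel_cutoff
        Minimum normal cancelled-target count; scores *below* it flag
        neglect.  Default 51 of 54 targets (documented placeholder for
        the battery's standardised cutoff).
    line_bisection_cutoff
        Rightward deviation at or beyond which the bisection flag is
        raised, in ``line_bisection_unit`` units.  Default 8.5 percent
        of line length (documented placeholder).
    line_cancel_asymmetry_min
        Minimum left-minus-right omission excess that flags neglect.
    landscape_omission_min
        Minimum number of omitted left-side landscape details that
        flags neglect.
    """

    star_cancel_cutoff: int = 51
    line_bisection_cutoff: float = 8.5
    line_cancel_asymmetry_min: int = 2
    landscape_omission_min: int = 1
    line_bisection_unit: str = "percent"

    def __post_init__(self) -> None:
        for name in (
            "star_cancel_cutoff",
            "line_bisection_cutoff",
            "line_cancel_asymmetry_min",
            "landscape_omission_min",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


DEFAULT_CUTOFFS = ScreeningCutoffs()


@dataclass(frozen=True)
class ScreeningClassification:
    """USN classification with the per-test flags that produced it."""

    label: str  # USN_PLUS or USN_MINUS
    line_cancellation_flag: bool
    star_cancellation_flag: bool
    line_bisection_flag: bool
    landscape_copy_flag: bool

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "line_cancellation": self.line_cancellation_flag,
            "star_cancellation": self.star_cancellation_flag,
            "line_bisection": self.line_bisection_flag,
            "landscape_copy": self.landscape_copy_flag,
        }


def classify_usn(
    result: ScreeningResult, cutoffs: ScreeningCutoffs = DEFAULT_CUTOFFS
) -> ScreeningClassification:
    """Classify a patient as USN+ or USN- from the screening battery.

    The overall label is the logical OR of the four per-test flags: a
    patient showing neglect on any single test is USN+.
    """
    line_cancel = (
        result.line_cancel_left_omissions - result.line_cancel_right_omissions
        >= cutoffs.line_cancel_asymmetry_min
    )
    star = result.star_cancel_score < cutoffs.star_cancel_cutoff
    bisection = result.line_bisection_deviation >= cutoffs.line_bisection_cutoff
    landscape = result.landscape_left_details_omitted >= cutoffs.landscape_omission_min
    label = USN_PLUS if (line_cancel or star or bisection or landscape) else USN_MINUS
    return ScreeningClassification(
        label=label,
        line_cancellation_flag=line_cancel,
        star_cancellation_flag=star,
        line_bisection_flag=bisection,
        landscape_copy_flag=landscape,
    )
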