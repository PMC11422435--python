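"""Synthetic cohort generation calibrated to published group quantiles.

The study design compares three groups — healthy controls (n=40) and
right-brain-damaged patients without (USN-, n=10) and with (USN+,
n=10) unilateral spatial neglect — on unit-level figure scores,
laterality indices, overlapping scores and a four-test screening
battery.  Raw per-subject data are not published, so this module
generates cohorts whose *derived-measure medians* match the published
group summaries, letting every downstream stage run end to end.

Distribution family (a modelling convenience, not a claim about
patients):

* unit correctness is drawn independently per unit from a side- and
  group-specific categorical distribution over {0, 0.5, 1, 1.5, 2},
  parameterised as Binomial(4, p)/2 so that each side's score is a
  Binomial sum with an exactly computable distribution;
* per-unit overlap counts are Poisson with side/group/task-specific
  means (complete and incomplete re-traces at a fixed 1:2 count
  ratio, i.e. half the expected overlap points from each);
* screening results are drawn so USN+ subjects fail at least one
  battery rule and USN-/healthy subjects pass all of them, which is
  checked against :func:`rocftrace.screening.classify_usn` at
  generation time.

Calibration searches the (p_left, p_right) grid for each group and
task so that the exact 0.5-quantiles of the implied total score and
laterality index match the target medians, and scales the Poisson
overlap rates so the exact median of the total overlapping score
matches its target with the left:right rate proportion taken from the
side targets.  Because the score distributions are Binomial sums and
the overlap distributions Poisson convolutions, the objective is
evaluated exactly rather than by simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom, poisson

from .scoring import (
    DEFAULT_PARTITION,
    UnitPartition,
    UnitScore,
    ValidationError,
)
from .screening import (
    DEFAULT_CUTOFFS,
    USN_MINUS,
    USN_PLUS,
    LANDSCAPE_DETAILS,
    ScreeningCutoffs,
    ScreeningResult,
    classify_usn,
)

__all__ = [
    "CATEGORIES",
    "GROUPS",
    "STUDY_GROUP_TARGETS",
    "CalibrationError",
    "GeneratorConfig",
    "GroupParams",
    "OverlapParams",
    "QuantileTargets",
    "ScreeningProfile",
    "SideParams",
    "SubjectRecord",
    "TaskParams",
    "calibrate_to_quantiles",
    "default_config",
    "generate_cohort",
]

CATEGORIES = (0.0, 0.5, 1.0, 1.5, 2.0)
GROUPS = ("healthy", "usn_minus", "usn_plus")
TASKS = ("copying", "tracing")

HALF_LEFT = 24  # left half-point maximum: 6 units x 4 half-points
HALF_RIGHT = 32
HALF_MID = 16


class CalibrationError(ValueError):
    """Calibration target outside the feasible range of the family."""


@dataclass(frozen=True)
class QuantileTargets:
    """Target medians for one group and task."""

    median_total: float
    median_li: float
    overlap_left_median: float
    overlap_right_median: float
    overlap_total_median: float

    def validate(self) -> None:
        if not 0.0 <= self.median_total <= 36.0:
            raise CalibrationError(
                f"median_total must be in [0, 36], got {self.median_total}"
            )
        if self.median_li < 0.0:
            raise CalibrationError(f"median_li must be >= 0, got {self.median_li}")
        for name in ("overlap_left_median", "overlap_right_median", "overlap_total_median"):
            if getattr(self, name) < 0.0:
                raise CalibrationError(f"{name} must be >= 0")


#: Published group medians the default cohorts are calibrated to
#: (figure scores, laterality indices and overlapping scores per group
#: and task; copying-task overlap medians are all zero).
STUDY_GROUP_TARGETS: dict[str, dict[str, QuantileTargets]] = {
    "healthy": {
        "copying": QuantileTargets(36.0, 1.0, 0.0, 0.0, 0.0),
        "tracing": QuantileTargets(34.0, 1.0, 0.5, 0.0, 1.5),
    },
    "usn_minus": {
        "copying": QuantileTargets(34.0, 0.91, 0.0, 0.0, 0.0),
        "tracing": QuantileTargets(33.0, 0.86, 1.5, 1.0, 2.0),
    },
    "usn_plus": {
        "copying": QuantileTargets(33.5, 0.84, 0.0, 0.0, 0.0),
        "tracing": QuantileTargets(33.0, 0.84, 1.75, 2.0, 3.25),
    },
}


@dataclass(frozen=True)
class SideParams:
    """Per-unit correctness distribution for one side of the figure."""

    correctness_probs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        probs = np.asarray(self.correctness_probs, dtype=float)
        if probs.size != len(CATEGORIES) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise CalibrationError(
                "correctness_probs must be 5 non-negative values summing to 1"
            )


@dataclass(frozen=True)
class OverlapParams:
    """Per-unit Poisson means for complete and incomplete re-traces."""

    complete_rate: float
    incomplete_rate: float

    def __post_init__(self) -> None:
        if self.complete_rate < 0 or self.incomplete_rate < 0:
            raise CalibrationError("overlap rates must be >= 0")

    @property
    def mean_points(self) -> float:
        return self.complete_rate + 0.5 * self.incomplete_rate


@dataclass(frozen=True)
class TaskParams:
    left: SideParams
    right: SideParams
    mid: SideParams
    overlap_left: OverlapParams
    overlap_right: OverlapParams
    overlap_mid: OverlapParams


@dataclass(frozen=True)
class ScreeningProfile:
    """Probabilities of drawing each screening deficit for a subject.

    Order: line cancellation, star cancellation, line bisection,
    landscape copying.  All-zero means the subject passes every test;
    a USN+ profile draws each deficit independently and, if none
    fires, one is imposed (the battery *defines* group membership).
    """

    deficit_probs: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(not 0.0 <= p <= 1.0 for p in self.deficit_probs):
            raise CalibrationError("deficit probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GroupParams:
    copying: TaskParams
    tracing: TaskParams
    screening: ScreeningProfile


@dataclass(frozen=True)
class GeneratorConfig:
    group_sizes: dict[str, int]
    groups: dict[str, GroupParams]
    cutoffs: ScreeningCutoffs = DEFAULT_CUTOFFS
    partition: UnitPartition = DEFAULT_PARTITION
    calibration_report: dict | None = None

    def __post_init__(self) -> None:
        for g in GROUPS:
            if g not in self.group_sizes or g not in self.groups:
                raise CalibrationError(f"config missing group {g!r}")
            if self.group_sizes[g] < 0:
                raise CalibrationError("group sizes must be >= 0")


@dataclass
class SubjectRecord:
    """One synthetic subject: demographics, screening and unit scores."""

    subject_id: str
    group: str
    age: float
    sex: str
    education_years: int
    mmse: int
    weeks_since_onset: float | None
    diagnosis: str | None
    screening: ScreeningResult
    units: dict[str, tuple[UnitScore, ...]]


# ---------------------------------------------------------------------------
# exact quantile machinery

def _weighted_q50(values: np.ndarray, probs: np.ndarray) -> float:
    """0.5-quantile (lower convention) of a discrete distribution."""
    order = np.argsort(values, kind="stable")
    cdf = np.cumsum(probs[order])
    cdf /= cdf[-1]
    idx = int(np.searchsorted(cdf, 0.5))
    return float(values[order][idx])


@lru_cache(maxsize=1)
def _li_grid() -> tuple[np.ndarray, np.ndarray]:
    """LI values for every (left, right>0) half-point pair, with sort order."""
    i = np.arange(HALF_LEFT + 1)[:, None]
    j = np.arange(1, HALF_RIGHT + 1)[None, :]
    li = (4.0 * i) / (3.0 * j)  # (i/24)/(j/32)
    flat = li.ravel()
    return flat, np.argsort(flat, kind="stable")


def _li_q50(pmf_left: np.ndarray, pmf_right: np.ndarray) -> float:
    """Exact median LI, excluding the undefined right-score-zero mass."""
    joint = np.outer(pmf_left, pmf_right[1:]).ravel()
    values, order = _li_grid()
    cdf = np.cumsum(joint[order])
    total = cdf[-1]
    if total <= 0:
        raise CalibrationError("right score is zero almost surely; LI undefined")
    idx = int(np.searchsorted(cdf, 0.5 * total))
    return float(values[order][idx])


def _total_q50(pmf_left: np.ndarray, pmf_right: np.ndarray, pmf_mid: np.ndarray) -> float:
    pmf = np.convolve(np.convolve(pmf_left, pmf_right), pmf_mid)
    return _weighted_q50(np.arange(pmf.size) / 2.0, pmf)


def _overlap_points_pmf(mean_points: float, max_points: float = 60.0) -> np.ndarray:
    """PMF of total overlap points on a half-point grid.

    Complete re-traces C ~ Poisson(mean/2) contribute 1 point each,
    incomplete I ~ Poisson(mean) contribute 0.5; points = C + I/2.
    """
    grid = int(2 * max_points) + 1
    lam_c, lam_i = 0.5 * mean_points, float(mean_points)
    kmax = grid // 2
    pmf_c = np.zeros(grid)
    pmf_c[0 : 2 * kmax + 1 : 2] = poisson.pmf(np.arange(kmax + 1), lam_c)
    pmf_i = poisson.pmf(np.arange(grid), lam_i)
    return np.convolve(pmf_c, pmf_i)[:grid]


def _overlap_q50(mean_points: float) -> float:
    pmf = _overlap_points_pmf(mean_points)
    return _weighted_q50(np.arange(pmf.size) / 2.0, pmf)


# ---------------------------------------------------------------------------
# calibration

def _correctness_loss(
    p_left: float, p_right: float, targets: QuantileTargets
) -> tuple[float, float, float]:
    pmf_l = binom.pmf(np.arange(HALF_LEFT + 1), HALF_LEFT, p_left)
    pmf_r = binom.pmf(np.arange(HALF_RIGHT + 1), HALF_RIGHT, p_right)
    pmf_m = binom.pmf(np.arange(HALF_MID + 1), HALF_MID, p_right)
    li = _li_q50(pmf_l, pmf_r)
    tot = _total_q50(pmf_l, pmf_r, pmf_m)
    loss = abs(li - targets.median_li) + 0.02 * abs(tot - targets.median_total)
    return loss, li, tot


def _fit_correctness(targets: QuantileTargets) -> tuple[float, float, float, float]:
    """Grid-search (p_left, p_right) matching median total score and LI."""
    coarse = 1.0 - np.geomspace(5e-4, 0.5, 49)
    best = (math.inf, 0.0, 0.0, 0.0, 0.0)  # loss, pl, pr, li, tot
    for pl in coarse:
        for pr in coarse:
            loss, li, tot = _correctness_loss(pl, pr, targets)
            if loss < best[0]:
                best = (loss, pl, pr, li, tot)
    # refine around the coarse optimum
    _, pl0, pr0, _, _ = best
    spacing = np.diff(coarse)
    step = float(np.max(np.abs(spacing)))  # conservative local width
    fine_l = np.clip(np.linspace(pl0 - step, pl0 + step, 25), 1e-4, 1 - 1e-6)
    fine_r = np.clip(np.linspace(pr0 - step, pr0 + step, 25), 1e-4, 1 - 1e-6)
    for pl in fine_l:
        for pr in fine_r:
            loss, li, tot = _correctness_loss(pl, pr, targets)
            if loss < best[0]:
                best = (loss, pl, pr, li, tot)
    _, pl, pr, li, tot = best
    if abs(li - targets.median_li) > 0.1 or abs(tot - targets.median_total) > 2.0:
        raise CalibrationError(
            f"unattainable correctness targets (median total "
            f"{targets.median_total}, median LI {targets.median_li}): best "
            f"achievable medians are total {tot:.2f}, LI {li:.3f} under the "
            f"score maxima (left 12, right 16)"
        )
    return float(pl), float(pr), float(li), float(tot)


def _fit_overlaps(
    targets: QuantileTargets,
    n_left: int = 6,
    n_right: int = 8,
    n_mid: int = 4,
) -> tuple[OverlapParams, OverlapParams, OverlapParams, dict[str, float]]:
    """Scale Poisson overlap rates so the total-overlap median matches.

    Side rates keep the left:right proportion of the side targets (any
    shortfall of the total target relative to the side targets goes to
    the midline units); the single free scale is chosen so the exact
    median of the total overlapping score equals the target.
    """
    l_t, r_t, tot_t = (
        targets.overlap_left_median,
        targets.overlap_right_median,
        targets.overlap_total_median,
    )
    if tot_t == 0.0:
        zero = OverlapParams(0.0, 0.0)
        return zero, zero, zero, {"left": 0.0, "right": 0.0, "total": 0.0}
    weights = np.array([l_t, r_t, max(tot_t - l_t - r_t, 0.0)])
    if weights.sum() == 0:
        weights = np.array([0.0, 0.0, 1.0])
    weights = weights / weights.sum()

    scales = np.arange(0.05, max(4.0 * tot_t, 2.0) + 1e-9, 0.01)
    medians = np.array([_overlap_q50(s) for s in scales])
    hits = np.flatnonzero(np.abs(medians - tot_t) == np.abs(medians - tot_t).min())
    s_total = float(scales[hits[len(hits) // 2]])  # middle of the plateau

    means = s_total * weights  # expected points per side
    params = []
    for mean_side, n_units in zip(means, (n_left, n_right, n_mid)):
        m_unit = mean_side / n_units
        params.append(OverlapParams(complete_rate=0.5 * m_unit, incomplete_rate=m_unit))
    achieved = {
        "left": _overlap_q50(means[0]),
        "right": _overlap_q50(means[1]),
        "total": _overlap_q50(s_total),
    }
    return params[0], params[1], params[2], achieved


def _side_params(p: float) -> SideParams:
    return SideParams(tuple(binom.pmf(np.arange(5), 4, p)))


DEFAULT_SCREENING_PROFILES = {
    "healthy": ScreeningProfile(),
    "usn_minus": ScreeningProfile(),
    # sparse deficits so per-test sensitivities stay moderate while the
    # any-test rule always fires
    "usn_plus": ScreeningProfile(deficit_probs=(0.4, 0.45, 0.5, 0.4)),
}


def calibrate_to_quantiles(
    targets: Mapping[str, Mapping[str, QuantileTargets]] = STUDY_GROUP_TARGETS,
    group_sizes: Mapping[str, int] | None = None,
    cutoffs: ScreeningCutoffs = DEFAULT_CUTOFFS,
    partition: UnitPartition = DEFAULT_PARTITION,
) -> GeneratorConfig:
    """Build a generator configuration matching target group medians.

    For every group and task the unit-level correctness and overlap
    parameters are chosen so the exact medians of the implied derived
    measures match the targets; achieved-vs-target medians are stored
    in ``config.calibration_report``.
    """
    sizes = dict(group_sizes or {"healthy": 40, "usn_minus": 10, "usn_plus": 10})
    groups: dict[str, GroupParams] = {}
    report: dict = {}
    for group in GROUPS:
        if group not in targets:
            raise CalibrationError(f"no targets for group {group!r}")
        task_params: dict[str, TaskParams] = {}
        for task in TASKS:
            tgt = targets[group][task]
            tgt.validate()
            pl, pr, li_med, tot_med = _fit_correctness(tgt)
            ol_l, ol_r, ol_m, ol_achieved = _fit_overlaps(tgt)
            task_params[task] = TaskParams(
                left=_side_params(pl),
                right=_side_params(pr),
                mid=_side_params(pr),
                overlap_left=ol_l,
                overlap_right=ol_r,
                overlap_mid=ol_m,
            )
            report[f"{group}/{task}"] = {
                "p_left": pl,
                "p_right": pr,
                "target_median_total": tgt.median_total,
                "achieved_median_total": tot_med,
                "target_median_li": tgt.median_li,
                "achieved_median_li": li_med,
                "target_overlap_medians": {
                    "left": tgt.overlap_left_median,
                    "right": tgt.overlap_right_median,
                    "total": tgt.overlap_total_median,
                },
                "achieved_overlap_medians": ol_achieved,
            }
        groups[group] = GroupParams(
            copying=task_params["copying"],
            tracing=task_params["tracing"],
            screening=DEFAULT_SCREENING_PROFILES[group],
        )
    return GeneratorConfig(
        group_sizes=sizes,
        groups=groups,
        cutoffs=cutoffs,
        partition=partition,
        calibration_report=report,
    )


@lru_cache(maxsize=4)
def _default_config_cached(sizes: tuple[tuple[str, int], ...]) -> GeneratorConfig:
    return calibrate_to_quantiles(STUDY_GROUP_TARGETS, group_sizes=dict(sizes))


def default_config(group_sizes: Mapping[str, int] | None = None) -> GeneratorConfig:
    """The study-condition configuration: published-quantile calibration
    with group sizes healthy 40, USN- 10, USN+ 10 unless overridden."""
    sizes = dict(group_sizes or {"healthy": 40, "usn_minus": 10, "usn_plus": 10})
    return _default_config_cached(tuple(sorted(sizes.items())))


# ---------------------------------------------------------------------------
# generation

_DEMOGRAPHICS = {
    # (age mean, age sd), F proportion, mmse deficit Poisson mean;
    # MMSE deficits overlap across groups: demographics must not
    # separate the cohorts
    "healthy": ((60.0, 12.0), 19 / 40, 0.5),
    "usn_minus": ((55.0, 10.0), 0.2, 0.8),
    "usn_plus": ((56.0, 10.0), 0.2, 0.9),
}
_EDUCATION_YEARS = (9, 12, 13, 14, 15, 16)
_EDUCATION_PROBS = (0.1, 0.35, 0.1, 0.15, 0.1, 0.2)


def _draw_demographics(rng: np.random.Generator, group: str) -> dict:
    (age_mu, age_sd), f_prop, mmse_lam = _DEMOGRAPHICS[group]
    age = float(np.clip(rng.normal(age_mu, age_sd), 20.0, 80.0))
    sex = "F" if rng.random() < f_prop else "M"
    education = int(rng.choice(_EDUCATION_YEARS, p=_EDUCATION_PROBS))
    mmse = int(np.clip(30 - rng.poisson(mmse_lam), 24, 30))
    if group == "healthy":
        weeks, diagnosis = None, None
    else:
        weeks = float(np.round(np.clip(rng.lognormal(math.log(30.0), 1.2), 2.0, 400.0), 1))
        diagnosis = "infarction" if rng.random() < 0.25 else "hemorrhage"
    return {
        "age": round(age, 1),
        "sex": sex,
        "education_years": education,
        "mmse": mmse,
        "weeks_since_onset": weeks,
        "diagnosis": diagnosis,
    }


def _draw_normal_screening(
    rng: np.random.Generator, cutoffs: ScreeningCutoffs
) -> dict[str, float | int]:
    star = 54 - int(rng.binomial(3, 0.25))
    star = max(star, cutoffs.star_cancel_cutoff)
    bisection = float(
        np.clip(rng.normal(1.5, 2.5), -6.0, cutoffs.line_bisection_cutoff - 0.5)
    )
    left = int(rng.integers(0, 2))
    right = int(rng.integers(0, 2))
    if left - right >= cutoffs.line_cancel_asymmetry_min:
        left = right
    return {
        "line_cancel_left_omissions": left,
        "line_cancel_right_omissions": right,
        "star_cancel_score": star,
        "line_bisection_deviation": round(bisection, 2),
        "landscape_left_details_omitted": 0,
    }


def _draw_screening(
    rng: np.random.Generator,
    profile: ScreeningProfile,
    cutoffs: ScreeningCutoffs,
    intended: str,
) -> ScreeningResult:
    values = _draw_normal_screening(rng, cutoffs)
    if intended == USN_PLUS:
        probs = np.asarray(profile.deficit_probs, dtype=float)
        deficits = rng.random(4) < probs
        if not deficits.any():
            weights = probs if probs.sum() > 0 else np.ones(4)
            deficits[rng.choice(4, p=weights / weights.sum())] = True
        if deficits[0]:
            right = int(rng.poisson(0.3))
            left = min(18, right + cutoffs.line_cancel_asymmetry_min + int(rng.poisson(1.0)))
            values["line_cancel_left_omissions"] = left
            values["line_cancel_right_omissions"] = right
        if deficits[1]:
            values["star_cancel_score"] = max(
                15, cutoffs.star_cancel_cutoff - 1 - int(rng.poisson(3.0))
            )
        if deficits[2]:
            values["line_bisection_deviation"] = round(
                cutoffs.line_bisection_cutoff + abs(rng.normal(3.0, 4.0)), 2
            )
        if deficits[3]:
            values["landscape_left_details_omitted"] = min(
                LANDSCAPE_DETAILS, cutoffs.landscape_omission_min + int(rng.poisson(0.5))
            )
    result = ScreeningResult(**values)
    label = classify_usn(result, cutoffs).label
    if intended == USN_PLUS and label != USN_PLUS:
        # the battery defines group membership; impose the mildest deficit
        values["landscape_left_details_omitted"] = cutoffs.landscape_omission_min
        result = ScreeningResult(**values)
        label = classify_usn(result, cutoffs).label
    expected = USN_PLUS if intended == USN_PLUS else USN_MINUS
    if label != expected:
        raise RuntimeError(
            f"generated screening result classifies as {label}, expected {expected}"
        )
    return result


def _draw_units(
    rng: np.random.Generator, params: TaskParams, partition: UnitPartition
) -> tuple[UnitScore, ...]:
    sides = (
        (sorted(partition.left_units), params.left, params.overlap_left),
        (sorted(partition.right_units), params.right, params.overlap_right),
        (sorted(partition.unassigned_units), params.mid, params.overlap_mid),
    )
    units: list[UnitScore] = []
    for unit_ids, side, overlap in sides:
        n = len(unit_ids)
        correctness = rng.choice(len(CATEGORIES), size=n, p=side.correctness_probs)
        complete = rng.poisson(overlap.complete_rate, size=n)
        incomplete = rng.poisson(overlap.incomplete_rate, size=n)
        for uid, c, co, inc in zip(unit_ids, correctness, complete, incomplete):
            units.append(
                UnitScore(
                    unit_id=int(uid),
                    correctness=CATEGORIES[int(c)],
                    complete_overlaps=int(co),
                    incomplete_overlaps=int(inc),
                )
            )
    return tuple(sorted(units, key=lambda u: u.unit_id))


_ID_PREFIX = {"healthy": "H", "usn_minus": "N", "usn_plus": "P"}


def generate_cohort(
    config: GeneratorConfig, seed: int = 0
) -> list[SubjectRecord]:
    """Generate a full cohort reproducibly from ``seed``.

    Subjects are emitted group by group (healthy, USN-, USN+) with
    unit-level scores for both tasks, screening results consistent with
    the generating group, and demographics.  The same seed always
    yields an identical cohort.
    """
    rng = np.random.default_rng(seed)
    cohort: list[SubjectRecord] = []
    for group in GROUPS:
        params = config.groups[group]
        intended = USN_PLUS if group == "usn_plus" else USN_MINUS
        for i in range(config.group_sizes[group]):
            demo = _draw_demographics(rng, group)
            screening = _draw_screening(rng, params.screening, config.cutoffs, intended)
            units = {
                "copying": _draw_units(rng, params.copying, config.partition),
                "tracing": _draw_units(rng, params.tracing, config.partition),
            }
            cohort.append(
                SubjectRecord(
                    subject_id=f"{_ID_PREFIX[group]}{i + 1:03d}",
                    group=group,
                    screening=screening,
                    units=units,
                    **demo,
                )
            )
    return cohort
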