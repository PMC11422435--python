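"""ROC analysis of candidate neglect-detection measures.

Each candidate measure (screening scores, figure scores, laterality
indices, overlapping scores) is evaluated against the USN+/USN- labels
of the right-brain-damaged patients.  A measure's *orientation* states
which side of the scale indicates neglect: scores and laterality
indices are low in neglect (``lower_indicates_USN``), overlapping
scores are high (``higher_indicates_USN``).

The AUC is the Mann-Whitney kernel probability that a USN+ patient's
value lies on the neglect side of a USN- patient's, ties counting 0.5;
its confidence interval uses DeLong's structural-components variance
estimator with a normal approximation, truncated to [0, 1].  The
reported cutoff is the midpoint between adjacent observed values whose
operating point lies closest (Euclidean distance) to the top-left ROC
corner; values equal to the cutoff count as on the neglect side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_curve as _sk_roc_curve

from .scoring import ValidationError

__all__ = [
    "HIGHER_INDICATES_USN",
    "LOWER_INDICATES_USN",
    "CutoffResult",
    "RocResult",
    "accuracy_band",
    "auc_mannwhitney",
    "auc_with_delong_ci",
    "evaluate_measure",
    "pct_beyond_cutoff",
    "roc_curve",
    "select_cutoff",
]

LOWER_INDICATES_USN = "lower_indicates_USN"
HIGHER_INDICATES_USN = "higher_indicates_USN"


def _validate(scores, labels, orientation, require_both=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if np.any(np.isnan(scores)):
        raise ValidationError("scores contain missing values; exclude them first")
    if orientation not in (LOWER_INDICATES_USN, HIGHER_INDICATES_USN):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be 0 (USN-) or 1 (USN+)")
    if require_both and (labels.sum() == 0 or labels.sum() == labels.size):
        raise ValidationError("both classes must be present")
    return scores, labels


def _oriented(scores: np.ndarray, orientation: str) -> np.ndarray:
    """Map scores so that larger oriented values indicate more neglect."""
    return -scores if orientation == LOWER_INDICATES_USN else scores


def roc_curve(
    scores: Sequence[float], labels: Sequence[int], orientation: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empirical ROC curve over all distinct thresholds.

    Returns (fpr, tpr, cutoffs) where ``cutoffs`` are on the original
    measure scale; tied values cross each threshold simultaneously.
    """
    scores, labels = _validate(scores, labels, orientation)
    fpr, tpr, thresholds = _sk_roc_curve(
        labels, _oriented(scores, orientation), drop_intermediate=False
    )
    cutoffs = -thresholds if orientation == LOWER_INDICATES_USN else thresholds
    return fpr, tpr, cutoffs


def auc_mannwhitney(
    scores: Sequence[float], labels: Sequence[int], orientation: str
) -> float:
    """AUC as the Mann-Whitney pair-probability kernel (ties count 0.5)."""
    scores, labels = _validate(scores, labels, orientation)
    oriented = _oriented(scores, orientation)
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float(np.mean((diff > 0) + 0.5 * (diff == 0)))


def auc_with_delong_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong normal-approximation confidence interval.

    The variance is var(V10)/m + var(V01)/n where V10/V01 are the
    structural components (per-positive and per-negative mean kernel
    values).  Under perfect separation the variance collapses to zero;
    a warning is issued and the CI degenerates to the point estimate.
    """
    scores, labels = _validate(scores, labels, orientation)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValidationError("need at least 2 subjects per class")
    oriented = _oriented(scores, orientation)
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    kernel = ((pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])).astype(
        float
    )
    auc = float(kernel.mean())
    v10 = kernel.mean(axis=1)  # one structural component per positive
    v01 = kernel.mean(axis=0)  # one per negative
    var = v10.var(ddof=1) / pos.size + v01.var(ddof=1) / neg.size
    if var <= 0:
        warnings.warn(
            "degenerate DeLong variance (perfect separation); CI collapses to "
            "the point estimate",
            stacklevel=2,
        )
        return auc, (auc, auc)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    inequality: str  # "<" when lower values indicate neglect, ">" otherwise
    sensitivity: float
    specificity: float
    distance: float  # Euclidean distance from (sens, spec) = (1, 1)


def _beyond(scores: np.ndarray, cutoff: float, orientation: str) -> np.ndarray:
    """Mask of values on the neglect side of the cutoff (ties inclusive)."""
    if orientation == LOWER_INDICATES_USN:
        return scores <= cutoff
    return scores >= cutoff


def select_cutoff(
    scores: Sequence[float], labels: Sequence[int], orientation: str
) -> CutoffResult:
    """Cutoff closest to the top-left ROC corner (perfect operation).

    Candidate cutoffs are the midpoints between adjacent distinct
    observed values plus one candidate beyond each extreme; the chosen
    candidate minimises sqrt((1-sens)^2 + (1-spec)^2).  Ties are broken
    deterministically: higher sensitivity first, then higher
    specificity, then the smaller cutoff value.
    """
    scores, labels = _validate(scores, labels, orientation)
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    pos = labels == 1
    neg = ~pos
    best: CutoffResult | None = None
    for c in candidates:
        beyond = _beyond(scores, c, orientation)
        sens = float(beyond[pos].mean())
        spec = float((~beyond[neg]).mean())
        dist = math.hypot(1.0 - sens, 1.0 - spec)
        cand = CutoffResult(
            cutoff=float(c),
            inequality="<" if orientation == LOWER_INDICATES_USN else ">",
            sensitivity=sens,
            specificity=spec,
            distance=dist,
        )
        if best is None or (cand.distance, -cand.sensitivity, -cand.specificity, cand.cutoff) < (
            best.distance,
            -best.sensitivity,
            -best.specificity,
            best.cutoff,
        ):
            best = cand
    assert best is not None
    return best


def pct_beyond_cutoff(
    scores: Sequence[float], cutoff: float, orientation: str
) -> float:
    """Percent of all given patients on the neglect side of the cutoff."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValidationError("no scores given")
    return float(100.0 * _beyond(scores, cutoff, orientation).mean())


def accuracy_band(auc: float) -> str:
    """Qualitative diagnostic-accuracy band for an AUC value.

    AUC >= 0.9 is highly accurate, 0.7-0.9 moderately accurate,
    0.5-0.7 rather inaccurate (boundaries assigned to the higher
    band); AUC <= 0.5 is a chance-level result.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC must be in [0, 1], got {auc!r}")
    if auc >= 0.9:
        return "high"
    if auc >= 0.7:
        return "moderate"
    if auc > 0.5:
        return "rather_inaccurate"
    return "chance"


@dataclass(frozen=True)
class RocResult:
    """Full diagnostic evaluation of one candidate measure."""

    measure_name: str
    orientation: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    inequality: str
    sensitivity: float
    specificity: float
    pct_beyond_cutoff: float
    accuracy_band: str

    def as_dict(self) -> dict[str, float | str]:
        return {
            "measure": self.measure_name,
            "orientation": self.orientation,
            "cutoff": self.cutoff,
            "inequality": self.inequality,
            "pct_beyond_cutoff": self.pct_beyond_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "accuracy_band": self.accuracy_band,
        }


def evaluate_measure(
    measure_name: str,
    scores: Sequence[float],
    labels: Sequence[int],
    orientation: str,
    level: float = 0.95,
) -> RocResult:
    """Assemble the complete ROC evaluation for one measure."""
    auc, (lo, hi) = auc_with_delong_ci(scores, labels, orientation, level=level)
    cut = select_cutoff(scores, labels, orientation)
    pct = pct_beyond_cutoff(scores, cut.cutoff, orientation)
    return RocResult(
        measure_name=measure_name,
        orientation=orientation,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=cut.cutoff,
        inequality=cut.inequality,
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
        pct_beyond_cutoff=pct,
        accuracy_band=accuracy_band(auc),
    )
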