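"""Group-comparison statistics for the figure-tracing study design.

The analysis chain mirrors standard practice for small clinical
samples with bounded, heavily tied scores: a Shapiro-Wilk normality
gate routes measures to nonparametric tests; three-group comparisons
use Kruskal-Wallis followed by pairwise Mann-Whitney U tests with Holm
step-down correction; pairwise effect sizes are reported as r.

Two conventions for r are provided.  The default derives r = |z|/sqrt(N)
from the tie-corrected normal approximation of the Mann-Whitney U
statistic; the literal formula r = sqrt(t^2/(t^2+df)) is also exposed
(`effect_size_r`) for analyses that carry a t-type statistic.  Which of
the two a given published table used is generally not recoverable; both
are documented, neither is asserted as "the" published convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .scoring import ValidationError

__all__ = [
    "CorrelationScreen",
    "GroupComparison",
    "PairwiseResult",
    "compare_groups",
    "correlation_screen",
    "demographics_table",
    "effect_size_r",
    "fisher_exact_rxc",
    "holm_adjust",
    "mannwhitney_u_z_r",
    "normality_gate",
]

ALPHA = 0.05  # fixed study-wide significance level


def normality_gate(groups: Mapping[str, Sequence[float]], alpha: float = ALPHA) -> str:
    """Decide between parametric and nonparametric testing.

    Returns ``"nonparametric"`` if any group rejects Shapiro-Wilk
    normality at ``alpha`` (or has zero variance, with a warning),
    otherwise ``"parametric"``.  Groups need at least 3 observations.
    """
    if not groups:
        raise ValidationError("normality_gate requires at least one group")
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size < 3:
            raise ValidationError(
                f"group {name!r} has {arr.size} non-missing values; need >= 3"
            )
        if np.ptp(arr) == 0:
            warnings.warn(
                f"group {name!r} has zero variance; treating as non-normal",
                stacklevel=2,
            )
            return "nonparametric"
        if sps.shapiro(arr).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def effect_size_r(t: float, df: float) -> float:
    """Effect size r = sqrt(t^2 / (t^2 + df)) for a t-type statistic."""
    if df <= 0:
        raise ValidationError(f"df must be > 0, got {df!r}")
    t2 = float(t) ** 2
    return math.sqrt(t2 / (t2 + df))


def mannwhitney_u_z_r(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Mann-Whitney U (of the first sample), its tie-corrected z, and r.

    z uses the mid-rank normal approximation with tie-corrected
    variance and no continuity correction; r = |z| / sqrt(n1 + n2).
    Degenerate data (all values identical) yield z = r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u1, 0.0, 0.0
    z = (u1 - mean_u) / math.sqrt(var_u)
    return u1, z, abs(z) / math.sqrt(n)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="holm")[1]


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    u_statistic: float
    p_raw: float
    p_holm: float
    effect_size_r: float


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus and pairwise comparison of one measure across groups."""

    measure_name: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: tuple[PairwiseResult, ...]
    n_per_group: dict[str, int]
    n_excluded: dict[str, int]
    summaries: dict[str, tuple[float, float, float]]  # median, Q1, Q3


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney p; exact when both n <= 8 and tie-free."""
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups: Mapping[str, Sequence[float]], measure_name: str = ""
) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus Holm-corrected pairwise tests.

    ``groups`` maps group name to that group's values for one measure
    (NaNs, e.g. undefined laterality indices, are excluded with a
    logged per-group count).  Requires at least three groups with
    n >= 2 each after exclusion.
    """
    if len(groups) < 3:
        raise ValidationError(f"need at least 3 groups, got {len(groups)}")
    cleaned: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        keep = arr[~np.isnan(arr)]
        excluded[name] = int(arr.size - keep.size)
        if excluded[name]:
            warnings.warn(
                f"{measure_name or 'measure'}: excluded {excluded[name]} undefined "
                f"value(s) from group {name!r}",
                stacklevel=2,
            )
        if keep.size < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 usable values")
        cleaned[name] = keep

    arrays = list(cleaned.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        omnibus_stat, omnibus_p = sps.kruskal(*arrays)

    names = list(cleaned)
    raw_ps: list[float] = []
    pair_stats: list[tuple[tuple[str, str], float, float]] = []
    for a, b in itertools.combinations(names, 2):
        x, y = cleaned[a], cleaned[b]
        if np.ptp(np.concatenate([x, y])) == 0:
            u, p = x.size * y.size / 2.0, 1.0
            r = 0.0
        else:
            u, p = _mannwhitney_p(x, y)
            _, _, r = mannwhitney_u_z_r(x, y)
        raw_ps.append(p)
        pair_stats.append(((a, b), u, r))
    adjusted = holm_adjust(raw_ps)

    pairwise = tuple(
        PairwiseResult(pair=pair, u_statistic=u, p_raw=p, p_holm=ph, effect_size_r=r)
        for (pair, u, r), p, ph in zip(pair_stats, raw_ps, adjusted)
    )
    summaries = {
        name: (
            float(np.median(arr)),
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)),
        )
        for name, arr in cleaned.items()
    }
    return GroupComparison(
        measure_name=measure_name,
        omnibus_statistic=float(omnibus_stat),
        omnibus_p=float(omnibus_p),
        pairwise=pairwise,
        n_per_group={name: int(arr.size) for name, arr in cleaned.items()},
        n_excluded=excluded,
        summaries=summaries,
    )


@dataclass(frozen=True)
class CorrelationScreen:
    """Spearman correlation matrix with a clinical-meaningfulness flag.

    With very small samples, moderate rank correlations arise by
    chance, so a correlation is flagged meaningful only when |rho|
    exceeds ``meaningful_threshold`` (default 0.8).
    """

    rho: pd.DataFrame  # rows: first measure set, cols: second measure set
    meaningful: pd.DataFrame  # same shape, boolean
    meaningful_threshold: float = 0.8


def correlation_screen(
    left: pd.DataFrame,
    right: pd.DataFrame,
    meaningful_threshold: float = 0.8,
) -> CorrelationScreen:
    """Spearman rho between every column of ``left`` and of ``right``.

    Rows must be paired observations (same subjects, same order);
    pairs with a missing value in either column are dropped pairwise.
    Requires at least 4 complete pairs per cell.
    """
    if len(left) != len(right):
        raise ValidationError(
            f"paired frames must have equal length, got {len(left)} and {len(right)}"
        )
    rho = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    for a in left.columns:
        for b in right.columns:
            x = np.asarray(left[a], dtype=float)
            y = np.asarray(right[b], dtype=float)
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < 4:
                raise ValidationError(
                    f"fewer than 4 complete pairs for ({a!r}, {b!r})"
                )
            rho.loc[a, b] = sps.spearmanr(x[mask], y[mask]).statistic
    meaningful = rho.abs() > meaningful_threshold
    return CorrelationScreen(
        rho=rho, meaningful=meaningful, meaningful_threshold=meaningful_threshold
    )


def fisher_exact_rxc(table: Sequence[Sequence[int]], max_tables: int = 2_000_000) -> float:
    """Exact Fisher test p-value for a small r x c contingency table.

    Enumerates all tables with the observed margins and sums the
    probabilities of tables no more probable than the observed one
    (two-sided, conditional hypergeometric null).  Intended for the
    small tables of clinical demographics; raises if the enumeration
    would exceed ``max_tables`` states.
    """
    obs = np.asarray(table, dtype=int)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValidationError("table must be a 2-D array of non-negative counts")
    if obs.shape == (2, 2):
        return float(sps.fisher_exact(obs)[1])
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = obs.sum()
    lognorm = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(n + 1)
    )

    def log_prob(cells: np.ndarray) -> float:
        return lognorm - gammaln(cells + 1.0).sum()

    obs_logp = log_prob(obs)
    total = 0.0
    count = 0

    r, c = obs.shape

    def recurse(row: int, remaining_cols: np.ndarray, filled: list[np.ndarray]) -> None:
        nonlocal total, count
        if row == r - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            count += 1
            if count > max_tables:
                raise ValidationError("table too large for exact enumeration")
            cells = np.vstack(filled + [last])
            lp = log_prob(cells)
            if lp <= obs_logp + 1e-10:
                total += math.exp(lp)
            return
        # enumerate compositions of row_sums[row] into c cells bounded by
        # the remaining column totals
        def fill(col: int, left: int, current: list[int]) -> None:
            if col == c - 1:
                if 0 <= left <= remaining_cols[col]:
                    recurse(
                        row + 1,
                        remaining_cols - np.array(current + [left]),
                        filled + [np.array(current + [left])],
                    )
                return
            for v in range(min(left, remaining_cols[col]) + 1):
                fill(col + 1, left - v, current + [v])

        fill(0, int(row_sums[row]), [])

    recurse(0, col_sums.copy(), [])
    return min(1.0, float(total))


def demographics_table(
    subjects: pd.DataFrame,
    group_col: str = "group",
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Group summary table with the matching hypothesis test per variable.

    Continuous variables are summarised as median (Q1-Q3) per group and
    compared by Kruskal-Wallis (3+ groups with data) or Mann-Whitney
    (2 groups); categorical variables as per-group counts compared by
    Fisher's exact test.  Variables observed in only some groups (e.g.
    stroke-specific fields) are compared across the groups that have
    them.
    """
    if group_col not in subjects.columns:
        raise ValidationError(f"missing group column {group_col!r}")
    group_names = list(dict.fromkeys(subjects[group_col]))
    if any((subjects[group_col] == g).sum() == 0 for g in group_names):
        raise ValidationError("empty group")
    rows = []
    for var in continuous:
        per_group: dict[str, str] = {}
        samples = []
        for g in group_names:
            vals = pd.to_numeric(
                subjects.loc[subjects[group_col] == g, var], errors="coerce"
            ).dropna()
            if len(vals):
                samples.append(np.asarray(vals, dtype=float))
                per_group[g] = (
                    f"{np.median(vals):.1f} "
                    f"({np.percentile(vals, 25):.1f}-{np.percentile(vals, 75):.1f})"
                )
            else:
                per_group[g] = "-"
        if len(samples) == 0:
            raise ValidationError(f"variable {var!r} has no observations")
        if len(samples) == 1:
            # observed in a single group (e.g. stroke-specific fields in a
            # patients-only subset): summarise without a between-group test
            rows.append({"variable": var, **per_group, "test": "-", "p": math.nan})
            continue
        if len(samples) == 2:
            test = "Mann-Whitney U"
            if np.ptp(np.concatenate(samples)) == 0:
                p = 1.0
            else:
                _, p = _mannwhitney_p(samples[0], samples[1])
        else:
            test = "Kruskal-Wallis"
            if np.ptp(np.concatenate(samples)) == 0:
                p = 1.0
            else:
                _, p = sps.kruskal(*samples)
        rows.append({"variable": var, **per_group, "test": test, "p": float(p)})
    for var in categorical:
        observed = subjects.dropna(subset=[var])
        levels = sorted(observed[var].unique())
        groups_with_data = [
            g for g in group_names if (observed[group_col] == g).any()
        ]
        counts = np.array(
            [
                [
                    int(
                        (
                            (observed[group_col] == g) & (observed[var] == level)
                        ).sum()
                    )
                    for level in levels
                ]
                for g in groups_with_data
            ]
        )
        per_group = {
            g: "/".join(str(v) for v in counts[i])
            for i, g in enumerate(groups_with_data)
        }
        for g in group_names:
            per_group.setdefault(g, "-")
        if len(groups_with_data) < 2 or len(levels) < 2:
            rows.append(
                {
                    "variable": f"{var} ({'/'.join(map(str, levels))})",
                    **{g: per_group[g] for g in group_names},
                    "test": "-",
                    "p": math.nan,
                }
            )
            continue
        p = fisher_exact_rxc(counts)
        rows.append(
            {
                "variable": f"{var} ({'/'.join(map(str, levels))})",
                **{g: per_group[g] for g in group_names},
                "test": "Fisher exact",
                "p": float(p),
            }
        )
    return pd.DataFrame(rows, columns=["variable", *group_names, "test", "p"])
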