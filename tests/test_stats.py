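"""Group statistics against independent oracles.

Oracles: a hand-executed Holm step-down, an exhaustive permutation
distribution for the Mann-Whitney test, and the closed form for the
effect size r.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rocftrace.scoring import ValidationError
from rocftrace.stats import (
    compare_groups,
    correlation_screen,
    demographics_table,
    effect_size_r,
    fisher_exact_rxc,
    holm_adjust,
    mannwhitney_u_z_r,
    normality_gate,
)


def holm_oracle(pvals: np.ndarray) -> np.ndarray:
    """Hand step-down: sort, multiply by (m - i), enforce monotonicity."""
    m = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        value = min(1.0, (m - rank) * pvals[idx])
        running = max(running, value)
        adjusted[idx] = running
    return adjusted


def mw_permutation_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of splits."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = mannwhitney_u_z_r(x, y)[0]
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        us.append(mannwhitney_u_z_r(pooled[mask], pooled[~mask])[0])
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestHolm:
    def test_hand_step_down_example(self):
        """Raw (0.01, 0.04, 0.03): sorted multipliers 3,2,1 give 0.03,
        0.06, 0.04; the monotonicity sweep lifts 0.04 to 0.06."""
        adjusted = holm_adjust([0.01, 0.04, 0.03])
        assert adjusted == pytest.approx([0.03, 0.06, 0.06])

    def test_matches_oracle_on_random_vectors(self, rng):
        for size in (1, 2, 3, 5, 8):
            for _ in range(40):
                pvals = rng.uniform(0, 1, size=size)
                assert holm_adjust(pvals) == pytest.approx(holm_oracle(pvals))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_monotone_and_bounded(self, pvals):
        adjusted = holm_adjust(pvals)
        assert np.all(adjusted <= 1.0)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValidationError):
            holm_adjust([0.5, 1.5])


class TestEffectSize:
    @pytest.mark.parametrize(
        "t, df, expected",
        [(0.0, 4, 0.0), (2.0, 4, math.sqrt(4 / 8)), (1e8, 10, 1.0)],
    )
    def test_closed_form(self, t, df, expected):
        assert effect_size_r(t, df) == pytest.approx(expected, abs=1e-7)

    def test_round_trip(self):
        """Solving r back for t^2 reproduces the input to 1e-12."""
        for t, df in [(0.3, 5), (2.7, 18), (11.0, 2)]:
            r = effect_size_r(t, df)
            t2 = r**2 * df / (1 - r**2)
            assert t2 == pytest.approx(t**2, rel=1e-12)

    def test_invalid_df(self):
        with pytest.raises(ValidationError):
            effect_size_r(1.0, 0)

    def test_z_based_r_bounded_and_zero_for_identical(self):
        _, z, r = mannwhitney_u_z_r([1, 1, 1], [1, 1, 1])
        assert (z, r) == (0.0, 0.0)
        _, _, r = mannwhitney_u_z_r([1, 2, 3, 10], [4, 5, 6, 7])
        assert 0.0 <= r < 1.0


class TestMannWhitney:
    def test_exact_p_matches_permutation_oracle(self, rng):
        """Tie-free samples with n <= 8 per group: the pipeline's exact p
        equals full enumeration of all group assignments."""
        for n1, n2 in [(4, 4), (5, 7), (8, 8), (3, 6)]:
            for _ in range(5):
                x = rng.normal(0, 1, n1)
                y = rng.normal(0.8, 1, n2)
                comp = compare_groups(
                    {"a": x, "b": y, "c": rng.normal(0, 1, 4)}, "m"
                )
                p_ab = next(p for p in comp.pairwise if p.pair == ("a", "b")).p_raw
                assert p_ab == pytest.approx(mw_permutation_oracle(x, y), abs=1e-12)


class TestCompareGroups:
    def test_identical_groups_are_null(self):
        groups = {g: [3.0, 3.0, 3.0, 3.0] for g in ("a", "b", "c")}
        comp = compare_groups(groups, "const")
        assert comp.omnibus_p == pytest.approx(1.0)
        assert all(p.p_holm == pytest.approx(1.0) for p in comp.pairwise)
        assert all(p.effect_size_r == 0.0 for p in comp.pairwise)

    def test_shifted_group_has_smallest_adjusted_p(self, rng):
        groups = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 1, 15),
            "c": rng.normal(4, 1, 15),
        }
        comp = compare_groups(groups, "shift")
        assert comp.omnibus_p < 0.001
        by_pair = {p.pair: p.p_holm for p in comp.pairwise}
        assert by_pair[("a", "c")] < by_pair[("a", "b")]
        assert by_pair[("b", "c")] < by_pair[("a", "b")]

    def test_nan_values_excluded_with_count(self):
        groups = {
            "a": [1.0, 2.0, np.nan, 3.0],
            "b": [2.0, 3.0, 4.0],
            "c": [5.0, 6.0, 7.0],
        }
        with pytest.warns(UserWarning, match="excluded 1"):
            comp = compare_groups(groups, "m")
        assert comp.n_excluded == {"a": 1, "b": 0, "c": 0}
        assert comp.n_per_group["a"] == 3

    def test_requires_three_groups(self):
        with pytest.raises(ValidationError):
            compare_groups({"a": [1, 2], "b": [3, 4]}, "m")


class TestNormalityGate:
    def test_skewed_scores_route_nonparametric(self, rng):
        groups = {
            g: np.minimum(36, 36 - rng.exponential(1.5, 30)).round(1)
            for g in ("a", "b", "c")
        }
        assert normality_gate(groups) == "nonparametric"

    def test_large_normal_samples_route_parametric(self, rng):
        groups = {g: rng.normal(0, 1, 200) for g in ("a", "b")}
        assert normality_gate(groups) == "parametric"

    def test_constant_group_warns_nonparametric(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert normality_gate({"a": [1.0, 1.0, 1.0]}) == "nonparametric"

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            normality_gate({"a": [1.0, 2.0]})


class TestCorrelationScreen:
    def test_self_correlation_is_meaningful(self, rng):
        x = pd.DataFrame({"m": rng.normal(size=20)})
        screen = correlation_screen(x, x.rename(columns={"m": "same"}))
        assert screen.rho.loc["m", "same"] == pytest.approx(1.0)
        assert bool(screen.meaningful.loc["m", "same"])

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=25)
        left = pd.DataFrame({"x": x})
        right = pd.DataFrame({"fx": np.exp(x)})  # strictly monotone
        screen = correlation_screen(left, right)
        assert screen.rho.loc["x", "fx"] == pytest.approx(1.0)

    def test_independent_pairs_not_meaningful(self, rng):
        left = pd.DataFrame({"x": rng.normal(size=20)})
        right = pd.DataFrame({"y": rng.normal(size=20)})
        screen = correlation_screen(left, right)
        assert abs(screen.rho.loc["x", "y"]) < 0.8
        assert not bool(screen.meaningful.loc["x", "y"])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            correlation_screen(
                pd.DataFrame({"a": [1, 2, 3, 4]}), pd.DataFrame({"b": [1, 2, 3]})
            )


class TestFisherExact:
    @pytest.mark.parametrize(
        "table",
        [
            [[5, 5], [5, 5]],
            [[2, 8], [3, 7]],
            [[1, 9], [8, 2]],
            [[0, 10], [10, 0]],
        ],
    )
    def test_2x2_matches_scipy(self, table):
        assert fisher_exact_rxc(table) == pytest.approx(
            sps.fisher_exact(table)[1], abs=1e-12
        )

    def test_balanced_diagnosis_split_is_null(self):
        """A 2/8 vs 3/7 diagnosis split carries no evidence (p = 1)."""
        assert fisher_exact_rxc([[2, 8], [3, 7]]) == pytest.approx(1.0)

    def test_3x2_table_reduces_to_2x2_when_one_row_empty(self):
        p3 = fisher_exact_rxc([[2, 8], [3, 7], [0, 0]])
        assert p3 == pytest.approx(fisher_exact_rxc([[2, 8], [3, 7]]), abs=1e-9)

    def test_3x2_extreme_table_is_significant(self):
        assert fisher_exact_rxc([[10, 0], [0, 10], [5, 5]]) < 0.001


class TestDemographics:
    def test_summary_table_with_tests(self, rng):
        n = 30
        frame = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["healthy"] * 14 + ["usn_minus"] * 8 + ["usn_plus"] * 8,
                "age": rng.normal(60, 10, n).round(1),
                "sex": rng.choice(["F", "M"], n),
                "weeks_since_onset": [np.nan] * 14 + list(rng.uniform(4, 200, 16).round(1)),
            }
        )
        table = demographics_table(
            frame,
            continuous=["age", "weeks_since_onset"],
            categorical=["sex"],
        )
        rows = dict(zip(table["variable"], table["test"]))
        assert rows["age"] == "Kruskal-Wallis"
        assert rows["weeks_since_onset"] == "Mann-Whitney U"  # patients only
        assert table["p"].between(0, 1).all()

    def test_identical_continuous_groups_null(self):
        frame = pd.DataFrame(
            {
                "subject_id": list("abcdefghi"),
                "group": ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3,
                "v": [5.0] * 9,
            }
        )
        table = demographics_table(frame, continuous=["v"])
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        frame = pd.DataFrame({"subject_id": [], "group": []})
        with pytest.raises(ValidationError):
            demographics_table(frame, continuous=["v"])
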