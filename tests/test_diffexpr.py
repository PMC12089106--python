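"""Unit and oracle tests for the group-comparison statistics.

The Mann-Whitney oracle enumerates every assignment of the pooled values to
the two groups and computes the two-sided permutation p directly; it never
touches the implementation's code path.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from fpkmkit import diffexpr as de
from fpkmkit.errors import ArgumentError, DegenerateVarianceError, UndefinedFoldError


# ---------------------------------------------------------------------------
# Independent oracle: exact two-sided Mann-Whitney by full enumeration
# ---------------------------------------------------------------------------

def _u_statistic(x, y):
    """U for x: pairs where x_i > y_j, halves for ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def brute_force_mwu_p(x, y):
    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = _u_statistic(x, y)
    us = []
    for idx in combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_statistic(xs, ys))
    us = np.array(us)
    n = len(us)
    p_le = np.sum(us <= u_obs) / n
    p_ge = np.sum(us >= u_obs) / n
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestFoldChange:
    def test_printed_group_means_give_seven_fold_down(self):
        fold, direction = de.fold_change(305, 46)
        assert fold == pytest.approx(6.63, abs=0.005)
        assert round(fold) == 7
        assert direction == "down"

    def test_other_printed_pair_reports_exact_ratio(self):
        fold, direction = de.fold_change(305, 35)
        assert fold == pytest.approx(8.71, abs=0.005)
        assert direction == "down"

    def test_equal_means_unchanged(self):
        assert de.fold_change(5, 5) == (1.0, "unchanged")

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedFoldError):
            de.fold_change(0, 0)

    def test_zero_denominator_flagged_not_infinite(self):
        with pytest.raises(UndefinedFoldError):
            de.fold_change(305, 0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ArgumentError):
            de.fold_change(-1, 5)

    @given(
        a=hst.floats(0.01, 1e5, allow_nan=False),
        b=hst.floats(0.01, 1e5, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_fold_at_least_one_and_swap_symmetric(self, a, b):
        fold, direction = de.fold_change(a, b)
        assert fold >= 1.0
        fold_swapped, direction_swapped = de.fold_change(b, a)
        assert fold_swapped == fold
        if direction == "up":
            assert direction_swapped == "down"
        elif direction == "down":
            assert direction_swapped == "up"


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = de.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_full_separation_exact(self):
        u, p = de.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ArgumentError):
            de.mann_whitney_u([], [1.0])

    def test_exact_close_to_approx_at_n6(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=6), rng.normal(size=6)
        _, p_exact = de.mann_whitney_u(x, y, mode="exact")
        _, p_approx = de.mann_whitney_u(x, y, mode="approx")
        assert abs(p_exact - p_approx) < 0.02

    @pytest.mark.parametrize(
        "n_x,n_y",
        [(n_x, n_y) for total in range(2, 11) for n_x in range(1, total) for n_y in [total - n_x]],
    )
    def test_exact_p_matches_brute_force_enumeration(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 100 + n_y)
        x = rng.normal(size=n_x)
        y = rng.normal(size=n_y)
        _, p = de.mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_auto_uses_approx_with_ties(self):
        # pooled sample has a tie, so auto must not take the exact route;
        # approx and auto must then agree exactly
        x, y = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        assert de.mann_whitney_u(x, y, mode="auto") == de.mann_whitney_u(x, y, mode="approx")


class TestWelchT:
    def test_identical_groups_t_zero_p_one(self):
        t, _, p = de.welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        _, _, p = de.welch_t([0, 0, 1], [10, 11, 12])
        assert p < 0.01

    def test_antisymmetric_in_swap(self):
        t1, df1, p1 = de.welch_t([0, 0, 1], [10, 11, 12])
        t2, df2, p2 = de.welch_t([10, 11, 12], [0, 0, 1])
        assert t2 == pytest.approx(-t1)
        assert df2 == pytest.approx(df1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_variance_names_group(self):
        with pytest.raises(DegenerateVarianceError, match="y"):
            de.welch_t([1, 2, 3], [5, 5, 5])

    def test_too_small_group_rejected(self):
        with pytest.raises(ArgumentError):
            de.welch_t([1], [1, 2])

    def test_matches_closed_form(self):
        x = np.array([1.0, 3.0, 4.0, 7.0])
        y = np.array([2.0, 2.5, 9.0])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / x.size + vy / y.size
        t_manual = (x.mean() - y.mean()) / np.sqrt(se2)
        df_manual = se2**2 / (
            (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
        )
        t, df, _ = de.welch_t(x, y)
        assert t == pytest.approx(t_manual)
        assert df == pytest.approx(df_manual)


class TestAnova:
    def test_identical_groups_null(self):
        res = de.bf_welch_anova(
            {"control": [1, 2, 3], "AD": [1, 2, 3], "PD": [1, 2, 3]}
        )
        assert res.p_welch == pytest.approx(1.0)
        assert res.p_brown_forsythe == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in res.per_comparison.values())

    def test_separated_third_group_detected(self):
        res = de.bf_welch_anova(
            {"control": [0, 0, 1], "AD": [0, 1, 1], "PD": [10, 11, 12]}
        )
        assert res.per_comparison["PD-vs-control"] < 0.05

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(11)
        groups = {g: rng.normal(size=5) for g in ("control", "AD", "PD")}
        res = de.bf_welch_anova(groups)
        for c in res.per_comparison:
            assert res.per_comparison[c] >= res.per_comparison_unadjusted[c] - 1e-12

    def test_fewer_than_three_groups_redirects(self):
        with pytest.raises(ArgumentError, match="two groups"):
            de.bf_welch_anova({"control": [1, 2], "AD": [3, 4]})

    def test_games_howell_option(self):
        res = de.bf_welch_anova(
            {"control": [0, 0, 1], "AD": [0, 1, 1], "PD": [10, 11, 12]},
            method="games-howell",
        )
        assert res.per_comparison["PD-vs-control"] < 0.05

    def test_welch_omnibus_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        groups = {g: rng.normal(loc=i, size=4 + i) for i, g in enumerate(("control", "AD", "PD"))}
        res = de.bf_welch_anova(groups)
        # independent recomputation of the Welch omnibus
        from scipy import stats

        arrays = [np.asarray(v) for v in groups.values()]
        k = len(arrays)
        n = np.array([a.size for a in arrays], float)
        m = np.array([a.mean() for a in arrays])
        v = np.array([a.var(ddof=1) for a in arrays])
        w = n / v
        mw = (w * m).sum() / w.sum()
        a_num = (w * (m - mw) ** 2).sum() / (k - 1)
        lam = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
        f = a_num / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
        p = stats.f.sf(f, k - 1, (k**2 - 1) / (3 * lam))
        assert res.p_welch == pytest.approx(p)


class TestStarLabel:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.03, "*"),
            (0.0049, "***"),
            (0.05, ""),
            (0.01, "*"),
            (0.005, "**"),
            (0.0099, "**"),
            (0.049999, "*"),
            (1.0, ""),
            (0.0, "***"),
        ],
    )
    def test_thresholds(self, p, expected):
        assert de.star_label(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            de.star_label(1.5)

    @given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_consistent_with_significance_counts(self, ps):
        labels = [de.star_label(p) for p in ps]
        assert sum(1 for s in labels if s != "") == de.significance_summary(ps, 0.05).n_significant
        assert sum(1 for s in labels if len(s) >= 2) == de.significance_summary(ps, 0.01).n_significant
        assert sum(1 for s in labels if len(s) == 3) == de.significance_summary(ps, 0.005).n_significant


class TestSignificanceSummary:
    def test_printed_proportion(self):
        ps = [0.01] * 2144 + [0.5] * (62704 - 2144)
        summary = de.significance_summary(ps, 0.05)
        assert summary.n_significant == 2144
        assert summary.proportion_percent == 3.4

    def test_all_one(self):
        s = de.significance_summary([1.0] * 10, 0.05)
        assert s.n_significant == 0 and s.proportion_percent == 0.0

    def test_all_zero(self):
        s = de.significance_summary([0.0] * 10, 0.05)
        assert s.n_significant == 10 and s.proportion_percent == 100.0

    def test_strict_inequality_at_alpha(self):
        s = de.significance_summary([0.05, 0.049999], 0.05)
        assert s.n_significant == 1

    def test_bad_alpha(self):
        with pytest.raises(ArgumentError):
            de.significance_summary([0.5], alpha=0.0)


class TestRankGenes:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "p_value", "fold_change"])

    def test_p_dominates(self):
        t = self._table([("g1", 0.01, 2.0), ("g2", 0.001, 1.1)])
        out = de.rank_genes(t)
        assert list(out["gene_id"]) == ["g2", "g1"]
        assert list(out["rank"]) == [1, 2]

    def test_fold_breaks_p_ties(self):
        t = self._table([("a", 0.01, 2.0), ("b", 0.01, 3.0)])
        assert list(de.rank_genes(t)["gene_id"]) == ["b", "a"]

    def test_full_tie_lexicographic_and_deterministic(self):
        t = self._table([("zz", 0.01, 2.0), ("aa", 0.01, 2.0)])
        out1 = de.rank_genes(t)
        out2 = de.rank_genes(t)
        assert list(out1["gene_id"]) == ["aa", "zz"]
        pd.testing.assert_frame_equal(out1, out2)

    def test_output_is_permutation_of_input(self):
        rng = np.random.default_rng(5)
        t = self._table(
            [(f"g{i}", rng.uniform(), rng.uniform(1, 10)) for i in range(30)]
        )
        out = de.rank_genes(t)
        assert sorted(out["gene_id"]) == sorted(t["gene_id"])
        assert list(out["rank"]) == list(range(1, 31))

    def test_nan_fold_sorts_last_within_p_tie(self):
        t = self._table([("a", 0.01, np.nan), ("b", 0.01, 1.5)])
        assert list(de.rank_genes(t)["gene_id"]) == ["b", "a"]


class TestCompareGroups:
    def test_table_shape_and_labels(self, cohort):
        matrix, meta = cohort
        out = de.compare_groups(matrix, meta, "control", "AD")
        assert len(out) == matrix.n_genes
        assert set(out["contrast"]) == {"AD-vs-control"}
        assert set(out["star_label"]) <= {"", "*", "**", "***"}
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()

    def test_mannwhitney_selectable(self, cohort):
        matrix, meta = cohort
        out = de.compare_groups(matrix, meta, "control", "PD", test="mannwhitney")
        assert set(out["test_name"]) == {"mannwhitney"}

    def test_bh_adjustment_is_extension(self, cohort):
        matrix, meta = cohort
        out = de.compare_groups(matrix, meta, adjust="bh")
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()

    def test_benjamini_hochberg_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        ps = rng.uniform(size=40)
        _, expected, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(de.benjamini_hochberg(ps), expected)
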