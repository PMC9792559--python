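"""Median centering, clustering, PCA, correlation, group tests, WB binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rppaqc.errors import UndefinedCorrelationError, ValidationError
from rppaqc.expression import (
    group_compare,
    group_compare_frame,
    hierarchical_cluster,
    median_center,
    pca_scores,
    pearson_r2,
    three_category_binning,
)


def _matrix(values, rows=None, cols=None):
    values = np.asarray(values, float)
    rows = rows or [f"Ab{i}" for i in range(values.shape[0])]
    cols = cols or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=rows, columns=cols)


class TestMedianCenter:
    def test_simple_row(self):
        out = median_center(_matrix([[1.0, 2.0, 3.0]]))
        assert out.iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 7)))
        once = median_center(m)
        twice = median_center(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_row_becomes_zero(self):
        out = median_center(_matrix([[4.0, 4.0, 4.0]]))
        assert (out.iloc[0] == 0).all()

    def test_every_centered_row_has_zero_median(self):
        m = _matrix(np.random.default_rng(1).normal(size=(6, 9)))
        out = median_center(m)
        assert np.allclose(out.median(axis=1), 0.0)

    def test_missing_entries_untouched(self):
        m = _matrix([[1.0, np.nan, 3.0]])
        out = median_center(m)
        assert np.isnan(out.iloc[0, 1])
        assert out.iloc[0, 0] == pytest.approx(-1.0)

    def test_empty_row_raises(self):
        with pytest.raises(ValidationError):
            median_center(_matrix([[np.nan, np.nan]]))


class TestHierarchicalCluster:
    def _block_matrix(self, rng, shift=5.0):
        # each block carries its own row profile, so columns correlate within
        # a block and anti-correlate across blocks
        base = rng.normal(size=(10, 8))
        profile = np.linspace(-1, 1, 10)[:, None]
        base[:, :4] += shift * profile
        base[:, 4:] -= shift * profile
        return _matrix(base)

    def test_top_split_separates_shifted_blocks(self):
        m = self._block_matrix(np.random.default_rng(0))
        res = hierarchical_cluster(m)
        a, b = res.col_top_split(list(m.columns))
        assert {frozenset(a), frozenset(b)} == {
            frozenset(m.columns[:4]),
            frozenset(m.columns[4:]),
        }

    def test_column_permutation_preserves_topology(self):
        rng = np.random.default_rng(2)
        m = self._block_matrix(rng)
        perm = rng.permutation(m.shape[1])
        shuffled = m.iloc[:, perm]
        a = hierarchical_cluster(m).col_top_split(list(m.columns))
        b = hierarchical_cluster(shuffled).col_top_split(list(shuffled.columns))
        assert {frozenset(x) for x in a} == {frozenset(x) for x in b}

    def test_deterministic_leaf_order(self):
        m = self._block_matrix(np.random.default_rng(3))
        r1 = hierarchical_cluster(m)
        r2 = hierarchical_cluster(m.copy())
        assert r1.row_order == r2.row_order
        assert r1.col_order == r2.col_order

    def test_zero_variance_row_named(self):
        m = _matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        with pytest.raises(ValidationError, match="Ab0"):
            hierarchical_cluster(m)

    def test_missing_values_need_imputation_flag(self):
        m = _matrix([[1.0, np.nan, 3.0], [2.0, 1.0, 0.5], [1.0, 3.0, 2.0]])
        with pytest.raises(ValidationError, match="impute"):
            hierarchical_cluster(m)
        res = hierarchical_cluster(m, impute_missing=True)
        assert len(res.row_order) == 3


class TestPca:
    def test_rank_one_matrix_pc1_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([1.0, -1.0, 0.5])
        m = _matrix(np.outer(u, v))
        _, evr = pca_scores(m, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_sign_convention_is_deterministic(self):
        m = _matrix(np.random.default_rng(4).normal(size=(6, 5)))
        s1, _ = pca_scores(m)
        s2, _ = pca_scores(m.copy())
        pd.testing.assert_frame_equal(s1, s2)

    def test_separated_groups_split_on_pc1(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(12, 10))
        base[:, 5:] += 8.0
        m = _matrix(base)
        scores, evr = pca_scores(m)
        signs = np.sign(scores["PC1"].to_numpy())
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[-1]
        assert evr[0] >= evr[1]

    def test_excess_components_clipped_with_warning(self):
        m = _matrix(np.random.default_rng(6).normal(size=(3, 4)))
        with pytest.warns(UserWarning, match="clipped"):
            scores, evr = pca_scores(m, n_components=10)
        assert scores.shape[1] <= 3

    def test_scores_orthogonal(self):
        m = _matrix(np.random.default_rng(7).normal(size=(8, 6)))
        scores, _ = pca_scores(m, n_components=3)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)


class TestPearson:
    def test_exact_affine_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = pearson_r2(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_five_point_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        res = pearson_r2(x, y)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.r2 == pytest.approx(r_oracle**2, abs=1e-12)
        assert res.n == 5

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = pearson_r2(x, y)
        shifted = pearson_r2(3.0 * x + 2.0, 0.5 * y - 7.0)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)

    def test_near_zero_for_independent_data(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=2000)
        y = rng.permutation(x)
        assert pearson_r2(x, y).r2 < 0.01

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_groups_give_zero_t(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        stat, p = group_compare(values, groups, "unpaired_t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_paired_constant_shift_is_degenerate(self):
        values = np.concatenate([np.arange(4.0), np.arange(4.0) + 2.0])
        groups = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValidationError, match="zero variance"):
            group_compare(values, groups, "paired_t")

    def test_paired_requires_equal_sizes(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        groups = np.array(["a", "a", "a", "b", "b"])
        with pytest.raises(ValidationError):
            group_compare(values, groups, "paired_t")

    def test_anova_two_groups_is_t_squared(self):
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8)])
        groups = np.array(["a"] * 8 + ["b"] * 8)
        t, p_t = group_compare(values, groups, "unpaired_t")
        f, p_f = group_compare(values, groups, "anova")
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_mann_whitney_matches_scipy(self):
        a = np.array([1.0, 5.0, 2.0, 8.0])
        b = np.array([3.0, 9.0, 4.0, 7.0])
        stat, p = group_compare(
            np.concatenate([a, b]), np.array(["x"] * 4 + ["y"] * 4), "mann_whitney"
        )
        ref = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert stat == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_unknown_test_rejected(self):
        with pytest.raises(ValidationError):
            group_compare(np.arange(4.0), np.array(["a", "a", "b", "b"]), "welch")

    def test_frame_wrapper_covers_all_rows(self):
        m = _matrix(np.random.default_rng(11).normal(size=(3, 6)))
        out = group_compare_frame(m, np.array(["a"] * 3 + ["b"] * 3), "unpaired_t")
        assert len(out) == 3
        assert set(out.columns) >= {"antibody_id", "statistic", "p_value"}


class TestThreeCategoryBinning:
    def test_stated_example(self):
        assert three_category_binning([0, 1, 2, 3, 4]) == [
            "zero",
            "low",
            "low",
            "high",
            "high",
        ]

    def test_even_count_balanced(self):
        got = three_category_binning([5.0, 1.0, 9.0, 3.0, 7.0, 11.0])
        assert got.count("low") == got.count("high") == 3

    def test_scale_invariance(self):
        x = [0.0, 1.5, 3.0, 0.7, 9.9]
        assert three_category_binning(x) == three_category_binning([v * 37.5 for v in x])

    def test_all_zero_warns_single_category(self):
        with pytest.warns(UserWarning):
            got = three_category_binning([0.0, 0.0, 0.0])
        assert got == ["zero"] * 3
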