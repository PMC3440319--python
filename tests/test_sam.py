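from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sarcsig import (
    DEConfig,
    compute_q_values,
    differential_expression,
    estimate_s0,
    fold_changes,
    permutation_null,
    sam_d_statistic,
    select_differential,
    union_analysis_set,
)
from sarcsig.simulate import ExpressionSimConfig, simulate_expression_cohort


def two_groups(g1, g2):
    X = np.array([g1 + g2], dtype=float)
    y = np.array([-1] * len(g1) + [1] * len(g2))
    return X, y


class TestDStatistic:
    def test_hand_example(self):
        X, y = two_groups([1, 2, 3], [3, 4, 5])
        d, s = sam_d_statistic(X, y, s0=0.0)
        assert s[0] == pytest.approx(np.sqrt(2 / 3), abs=1e-12)
        assert d[0] == pytest.approx(2.0 / np.sqrt(2 / 3), abs=1e-12)

    def test_equal_means_zero(self):
        X, y = two_groups([1, 2, 3], [3, 2, 1])
        d, _ = sam_d_statistic(X, y, s0=0.0)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_large_s0_shrinks_to_zero(self):
        X, y = two_groups([1, 2, 3], [10, 11, 12])
        d, _ = sam_d_statistic(X, y, s0=1e12)
        assert abs(d[0]) < 1e-10

    def test_zero_denominator_warns(self):
        X, y = two_groups([1.0, 1.0], [2.0, 2.0])
        with pytest.warns(UserWarning, match="zero"):
            d, _ = sam_d_statistic(X, y, s0=0.0)
        assert d[0] == 0.0

    def test_small_group_errors(self):
        X = np.array([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            sam_d_statistic(X, np.array([1, -1, -1]), s0=0.0)

    def test_matches_pooled_t_statistic(self, rng):
        """With s0=0, d is exactly the equal-variance two-sample t."""
        for _ in range(20):
            X = rng.normal(size=(30, 12))
            y = np.array([-1] * 6 + [1] * 6)
            d, _ = sam_d_statistic(X, y, s0=0.0)
            t = stats.ttest_ind(X[:, 6:], X[:, :6], axis=1, equal_var=True).statistic
            np.testing.assert_allclose(d, t, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_t_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 9))
        y = np.array([-1] * 4 + [1] * 5)
        d, _ = sam_d_statistic(X, y, s0=0.0)
        t = stats.ttest_ind(X[:, 4:], X[:, :4], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d, t, atol=1e-12)


class TestEstimateS0:
    def test_fixed_mode_passthrough(self, rng):
        cfg = DEConfig(s0_mode="fixed", s0_value=0.3)
        X = rng.normal(size=(120, 10))
        y = np.array([-1] * 5 + [1] * 5)
        m = _as_matrix(X)
        de = differential_expression(m, y, cfg)
        assert de.attrs["s0"] == 0.3

    def test_few_genes_fallback_median(self, rng):
        X = rng.normal(size=(20, 10))
        y = np.array([-1] * 5 + [1] * 5)
        with pytest.warns(UserWarning, match="median"):
            s0 = estimate_s0(X, y)
        _, s = sam_d_statistic(X, y, 0.0)
        assert s0 == pytest.approx(np.median(s))

    def test_variance_trend_gives_positive_s0(self):
        """On data where low-variance genes would dominate d, s0 > 0."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sd = rng.uniform(0.05, 2.0, size=400)
            X = rng.normal(0, sd[:, None], size=(400, 16))
            y = np.array([-1] * 8 + [1] * 8)
            if estimate_s0(X, y) > 0:
                hits += 1
        assert hits >= 18

    def test_finite_nonnegative_on_homoscedastic(self, rng):
        X = rng.normal(0, 1.0, size=(200, 12))
        y = np.array([-1] * 6 + [1] * 6)
        s0 = estimate_s0(X, y)
        assert np.isfinite(s0) and s0 >= 0


class TestPermutationNull:
    def test_exhaustive_three_vs_three(self, rng):
        X = rng.normal(size=(15, 6))
        y = np.array([-1] * 3 + [1] * 3)
        null = permutation_null(X, y, s0=0.1, n_permutations=100, seed=0)
        assert null.shape == (comb(6, 3), 15)

    def test_exhaustive_matches_bruteforce(self, rng):
        """All C(8,4) label arrangements reproduce a direct enumeration."""
        X = rng.normal(size=(12, 8))
        y = np.array([-1] * 4 + [1] * 4)
        null = permutation_null(X, y, s0=0.2, n_permutations=200, seed=0)
        expected = []
        for pos in combinations(range(8), 4):
            yy = -np.ones(8, dtype=int)
            yy[list(pos)] = 1
            d, _ = sam_d_statistic(X, yy, s0=0.2)
            expected.append(d)
        np.testing.assert_allclose(null, np.array(expected), atol=1e-12)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(10, 20))
        y = np.array([-1] * 10 + [1] * 10)
        a = permutation_null(X, y, 0.1, 50, seed=7)
        b = permutation_null(X, y, 0.1, 50, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_null_data_indistinguishable_from_pooled_null(self):
        """Observed d on null data looks like a draw from the permutation null."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 16))
            y = np.array([-1] * 8 + [1] * 8)
            d, _ = sam_d_statistic(X, y, 0.1)
            null = permutation_null(X, y, 0.1, 100, seed=seed)
            if stats.ks_2samp(d, null.ravel()).pvalue > 0.01:
                ok += 1
        assert ok >= 19


class TestQValues:
    def test_top_gene_zero_when_null_never_exceeds(self):
        d_obs = np.array([10.0, 1.0, 0.5])
        d_null = np.array([[0.4, 0.3, 0.2], [0.1, 0.2, 0.3]])
        q = compute_q_values(d_obs, d_null)
        assert q[0] == 0.0

    def test_monotone_nonincreasing_in_abs_d(self, rng):
        d_obs = rng.normal(size=200)
        d_null = rng.normal(size=(50, 200))
        q = compute_q_values(d_obs, d_null)
        order = np.argsort(-np.abs(d_obs))
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_conservative_pi0_not_smaller(self, rng):
        d_obs = rng.normal(size=100)
        d_null = rng.normal(size=(40, 100))
        q_est = compute_q_values(d_obs, d_null, pi0_mode="estimate")
        q_one = compute_q_values(d_obs, d_null, pi0_mode="one")
        assert (q_one >= q_est - 1e-12).all()

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            compute_q_values(np.array([1.0]), np.empty((0, 1)))


class TestFoldChanges:
    def test_doubling(self):
        X, y = two_groups([5.0, 5.0], [6.0, 6.0])
        assert fold_changes(X, y)[0] == pytest.approx(2.0)

    def test_identity(self):
        X, y = two_groups([5.0, 5.0], [5.0, 5.0])
        assert fold_changes(X, y)[0] == pytest.approx(1.0)

    def test_down_regulation_convention(self):
        # case mean lower by log2(1/0.63): FC = 0.63, the down direction
        shift = np.log2(0.63)
        X, y = two_groups([5.0, 5.0], [5.0 + shift, 5.0 + shift])
        assert fold_changes(X, y)[0] == pytest.approx(0.63, abs=1e-12)

    def test_linear_scale_input(self):
        X = np.array([[4.0, 4.0, 8.0, 8.0]])
        y = np.array([-1, -1, 1, 1])
        assert fold_changes(X, y, log2_input=False)[0] == pytest.approx(2.0)


class TestSelectDifferential:
    def _frame(self, fc, q):
        return pd.DataFrame({"fold_change": [fc], "q_value": [q]}, index=["G"])

    def test_down_regulated_selected(self):
        out = select_differential(self._frame(0.63, 0.0))
        assert bool(out["selected"].iloc[0])
        assert out["direction"].iloc[0] == "down"

    def test_fc_boundary_strict(self):
        out = select_differential(self._frame(1.40, 0.01))
        assert not bool(out["selected"].iloc[0])

    def test_q_boundary(self):
        out = select_differential(self._frame(2.0, 0.06))
        assert not bool(out["selected"].iloc[0])


class TestUnionAnalysisSet:
    def test_union_and_order(self):
        assert union_analysis_set(["A", "B"], ["B", "C"]) == ["A", "B", "C"]

    def test_empty_identity(self):
        assert union_analysis_set([], ["X", "Y"]) == ["X", "Y"]

    def test_disjoint_sizes(self):
        assert len(union_analysis_set(list("ABC"), list("DEFG"))) == 7


def _as_matrix(X):
    from sarcsig import ExpressionMatrix

    return ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"G{i}" for i in range(X.shape[0])],
            columns=[f"s{j}" for j in range(X.shape[1])],
        )
    )


class TestEndToEnd:
    def test_planted_genes_recovered_with_power(self):
        """Planted genes (1 log2 unit, noise 0.5, 20v20) are selected in
        >=90% of seeds; d ranking puts them on top."""
        recovered = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(7, 0.5, size=(200, 40))
            X[:10, 20:] += 1.0  # planted up-regulation in cases
            y = np.array([-1] * 20 + [1] * 20)
            de = differential_expression(_as_matrix(X), y, DEConfig(seed=seed))
            if de["selected"][:10].all():
                recovered += 1
        assert recovered >= int(0.9 * n_seeds)

    def test_differential_expression_deterministic(self, planted_cohort):
        m, ph, _ = planted_cohort
        samples = ph.select_samples(classes=["CS", "HC"])
        y = ph.binary_labels(samples, ["CS"], ["HC"])
        sub = m.subset_samples(samples)
        a = differential_expression(sub, y, DEConfig(seed=3))
        b = differential_expression(sub, y, DEConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)
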