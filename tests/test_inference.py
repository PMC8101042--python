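import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import herdsync as hs


def exhaustive_permutation_p(matrix, observed_stat):
    """Oracle: exact within-block permutation null of the Friedman statistic.

    Independently recomputes the tie-corrected statistic from its textbook
    definition for every within-block arrangement.
    """
    matrix = np.asarray(matrix, float)
    n, k = matrix.shape

    def tie_stat(x):
        r = stats.rankdata(x, axis=1)
        col = r.sum(axis=0)
        a1 = (r ** 2).sum()
        c1 = n * k * (k + 1) ** 2 / 4.0
        if a1 == c1:
            return 0.0
        return (k - 1) * ((col - n * (k + 1) / 2.0) ** 2).sum() / (a1 - c1)

    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=n):
        x = np.array([matrix[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if tie_stat(x) >= observed_stat - 1e-12:
            hits += 1
    return hits / total


class TestFriedman:
    def test_perfect_concordance_reaches_maximum(self):
        # every block strictly ordered the same way: statistic = n(k-1)
        n, k = 30, 4
        x = np.tile(np.arange(1, k + 1), (n, 1))
        res = hs.friedman_test(x)
        assert res.statistic == pytest.approx(n * (k - 1))
        assert res.p_value < 1e-15
        # without ties the uncorrected closed form agrees
        res_u = hs.friedman_test(x, tie_correction=False)
        assert res_u.statistic == pytest.approx(res.statistic)

    def test_constant_matrix_is_degenerate(self):
        res = hs.friedman_test(np.full((5, 4), 7.0))
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    @pytest.mark.parametrize(
        "matrix,perm_p",
        [
            # oracle p-values frozen from exhaustive enumeration of the
            # (3!)**4 = 1296 within-block arrangements
            ([[1, 2, 2], [3, 1, 1], [2, 2, 3], [1, 3, 2]], 0.7407407407407407),
            ([[5, 5, 1], [2, 4, 4], [3, 3, 3], [1, 2, 5]], 0.6666666666666666),
        ],
    )
    def test_tied_4x3_agrees_with_permutation_oracle(self, matrix, perm_p):
        res = hs.friedman_test(matrix)
        oracle = exhaustive_permutation_p(matrix, res.statistic)
        assert oracle == pytest.approx(perm_p)
        # chi-square approximation error at n = 4 blocks is substantial in
        # the mid-p range; 0.2 bounds it for these matrices
        assert abs(res.p_value - oracle) < 0.2

    @pytest.mark.parametrize(
        "matrix",
        [
            [[1, 2, 2], [3, 1, 1], [2, 2, 3], [1, 3, 2]],
            [[0, 4, 9], [3, 3, 3], [8, 1, 2], [5, 6, 7], [2, 2, 0]],
            [[12, 10, 8, 5], [15, 14, 9, 9], [7, 7, 7, 6]],
        ],
    )
    def test_statistic_matches_scipy_reference(self, matrix):
        # scipy's friedmanchisquare is an independent tie-corrected
        # implementation of the same statistic
        matrix = np.asarray(matrix, float)
        ours = hs.friedman_test(matrix)
        ref = stats.friedmanchisquare(*matrix.T)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, size=(6, 4)).astype(float)
        res = hs.friedman_test(x)
        res_t = hs.friedman_test(np.exp(x / 3.0) + 5.0)
        assert res_t.statistic == pytest.approx(res.statistic)

    def test_null_level_on_iid_matrices(self):
        # rejection rate at alpha = .05 over iid continuous 30 x 4 matrices
        rng = np.random.default_rng(99)
        n_rep = 1000
        rejections = 0
        for _ in range(n_rep):
            if hs.friedman_test(rng.normal(size=(30, 4))).p_value < 0.05:
                rejections += 1
        lo = stats.binom.ppf(0.005, n_rep, 0.05)
        hi = stats.binom.ppf(0.995, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            hs.friedman_test(np.ones((1, 4)))
        with pytest.raises(ValueError):
            hs.friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))


def conover_oracle(matrix):
    """Independent textbook computation of the Conover pairwise statistics."""
    x = np.asarray(matrix, float)
    n, k = x.shape
    r = stats.rankdata(x, axis=1)
    R = r.sum(axis=0)
    A1 = float((r ** 2).sum())
    C1 = n * k * (k + 1) ** 2 / 4.0
    T1 = (k - 1) * float(((R - n * (k + 1) / 2.0) ** 2).sum()) / (A1 - C1)
    df = (n - 1) * (k - 1)
    denom = math.sqrt(2.0 * n * (A1 - C1) * (1.0 - T1 / (n * (k - 1))) / df)
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        t = abs(R[i] - R[j]) / denom
        out[(i, j)] = 2.0 * stats.t.sf(t, df)
    return out


class TestConover:
    def test_identical_columns_are_not_distinguished(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 15, size=(12, 4)).astype(float)
        x[:, 1] = x[:, 0]
        res = hs.conover_posthoc(x)
        row = res.table[(res.table.treatment_a == "col0")
                        & (res.table.treatment_b == "col1")]
        assert float(row.raw_p.iloc[0]) > 0.95

    def test_maximal_concordance_all_pairs_significant(self):
        x = np.tile(np.arange(1, 5), (30, 1)) + \
            np.random.default_rng(0).normal(0, 0.01, (30, 4))
        res = hs.conover_posthoc(x)
        assert (res.table.adjusted_p < 0.05).all()

    def test_matches_independent_textbook_oracle(self):
        rng = np.random.default_rng(21)
        x = rng.integers(0, 16, size=(10, 4)).astype(float)
        res = hs.conover_posthoc(x, p_adjust="none")
        oracle = conover_oracle(x)
        names = [f"col{j}" for j in range(4)]
        for (i, j), p in oracle.items():
            row = res.table[(res.table.treatment_a == names[i])
                            & (res.table.treatment_b == names[j])]
            assert float(row.raw_p.iloc[0]) == pytest.approx(min(p, 1.0))

    def test_column_permutation_preserves_p_value_set(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 15, size=(8, 4)).astype(float)
        res = hs.conover_posthoc(x)
        perm = [2, 0, 3, 1]
        res_p = hs.conover_posthoc(x[:, perm])
        assert np.allclose(sorted(res.table.adjusted_p),
                           sorted(res_p.table.adjusted_p))

    def test_degenerate_matrix_gives_all_ones(self):
        res = hs.conover_posthoc(np.full((6, 4), 3.0))
        assert (res.table.adjusted_p == 1.0).all()

    def test_bonferroni_bounds(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 15, size=(10, 4)).astype(float)
        res = hs.conover_posthoc(x)
        assert (res.table.adjusted_p >= res.table.raw_p - 1e-15).all()
        assert (res.table.adjusted_p <= 1.0).all()
        assert len(res.table) == 6 and res.df == 27


class TestSignedRank:
    def test_all_values_above_median_exact_enumeration(self):
        # 5 positive differences: one of 2**5 sign patterns each way
        values = [0.6, 0.7, 0.8, 0.9, 1.0]
        res = hs.one_sample_signed_rank(values, 0.516)
        assert res.method == "exact"
        assert res.statistic == 15.0  # sum of ranks 1..5
        assert res.p_value == pytest.approx(2 / 32)
        one_sided = hs.one_sample_signed_rank(values, 0.516,
                                              alternative="greater")
        assert one_sided.p_value == pytest.approx(1 / 32)

    def test_symmetric_sample_is_null(self):
        mu0 = 0.5
        values = [mu0 + d for d in (-0.3, -0.2, -0.1, 0.1, 0.2, 0.3)]
        res = hs.one_sample_signed_rank(values, mu0)
        # W+ at its null mean n(n+1)/4
        assert res.statistic == pytest.approx(6 * 7 / 4)
        assert res.p_value == pytest.approx(1.0, abs=0.07)

    def test_single_nonzero_value(self):
        res = hs.one_sample_signed_rank([0.7], 0.516)
        assert res.p_value == pytest.approx(1.0)

    def test_all_values_equal_median_is_degenerate(self):
        res = hs.one_sample_signed_rank([0.5, 0.5, 0.5], 0.5)
        assert res.degenerate and res.p_value == 1.0 and res.n_nonzero == 0

    def test_tied_large_sample_uses_corrected_approximation(self):
        rng = np.random.default_rng(8)
        values = rng.integers(0, 16, size=30) / 15.0
        res = hs.one_sample_signed_rank(values, 0.516)
        assert res.method == "approx"
        ref = stats.wilcoxon(np.asarray(values) - 0.516, correction=True,
                             method="approx")
        assert res.p_value == pytest.approx(ref.pvalue)
        assert 0.0 <= res.chi_square_1_p <= 1.0
        assert res.chi_square_1 >= 0.0

    def test_chi_square_companion_matches_squared_z(self):
        values = [0.6, 0.7, 0.8, 0.9, 1.0]
        res = hs.one_sample_signed_rank(values, 0.516)
        # z = (|15 - 7.5| - 0.5) / sqrt(5*6*11/24)
        z = (abs(15 - 5 * 6 / 4) - 0.5) / math.sqrt(5 * 6 * 11 / 24)
        assert res.chi_square_1 == pytest.approx(z * z)
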