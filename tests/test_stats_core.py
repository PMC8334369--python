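import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirnome.stats_core import (
    bh_adjust,
    binomial_two_sided,
    chi2_independence,
    fixed_effect_meta,
    hwe_exact,
    kendall_tau,
    kendall_tau_test,
    kruskal_wallis,
    linear_fit,
    logistic_fit,
    spearman_rho,
)


def bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_j >= p_i of p_j * n / rank_j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    for i, idx in enumerate(order):
        q[idx] = min(min(p[order[j]] * n / (j + 1) for j in range(i, n)), 1.0)
    return q


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_spec_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.3] * 7) == pytest.approx([0.3] * 7)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="index 2"):
            bh_adjust([0.1, 0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=50, deadline=None)
    def test_never_below_raw_and_monotone(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBinomialTwoSided:
    def test_printed_8_of_29(self):
        assert binomial_two_sided(8, 29).p_value == pytest.approx(0.024, abs=5e-4)

    def test_printed_bound_5_of_13(self):
        assert binomial_two_sided(5, 13).p_value == pytest.approx(0.581, abs=5e-4)
        assert binomial_two_sided(5, 13).p_value > 0.58

    def test_trivial_k0_n1(self):
        assert binomial_two_sided(0, 1).p_value == 1.0

    @pytest.mark.parametrize("k,n", [(0, 10), (3, 11), (8, 29), (5, 13)])
    def test_symmetry_at_half(self, k, n):
        assert binomial_two_sided(k, n).p_value == pytest.approx(
            binomial_two_sided(n - k, n).p_value
        )

    @pytest.mark.parametrize("k,n", [(2, 10), (8, 29), (15, 30)])
    def test_matches_scipy_exact(self, k, n):
        assert binomial_two_sided(k, n).p_value == pytest.approx(
            sps.binomtest(k, n, 0.5).pvalue, rel=1e-12
        )

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            binomial_two_sided(0, 0)


class TestChi2Independence:
    def test_printed_target_table(self):
        res = chi2_independence([[1305, 773], [1207, 888]])
        assert res.p_value == pytest.approx(6.2e-4, abs=5e-5)
        assert res.df == 1

    def test_identical_rows_independent(self):
        res = chi2_independence([[10, 20, 30], [10, 20, 30]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_yates_flag(self):
        plain = chi2_independence([[12, 5], [3, 9]])
        corrected = chi2_independence([[12, 5], [3, 9]], yates=True)
        assert corrected.statistic < plain.statistic

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_independence([[0, 0], [5, 5]])

    def test_against_permutation_oracle(self):
        # 2x2 with fixed margins: null distribution of the statistic by
        # hypergeometric resampling of the top-left cell; the mid-p rule
        # handles the atom the continuous approximation splits
        table = np.array([[1020, 980], [980, 1020]])
        observed = chi2_independence(table).statistic
        rng = np.random.default_rng(0)
        r1, r2 = table.sum(axis=1)
        c1 = table.sum(axis=0)[0]
        n = table.sum()
        a = rng.hypergeometric(r1, r2, c1, size=200_000)
        tables = np.stack([a, r1 - a, c1 - a, r2 - (c1 - a)], axis=1).reshape(-1, 2, 2)
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        stats_null = ((tables - exp) ** 2 / exp).sum(axis=(1, 2))
        p_perm = (stats_null > observed + 1e-9).mean() + 0.5 * (
            np.abs(stats_null - observed) <= 1e-9
        ).mean()
        assert chi2_independence(table).p_value == pytest.approx(p_perm, abs=0.01)

    def test_permutation_invariance(self):
        t = np.array([[5, 9, 2], [7, 3, 11]])
        base = chi2_independence(t).statistic
        assert chi2_independence(t[:, [2, 0, 1]]).statistic == pytest.approx(base)
        assert chi2_independence(t[::-1]).statistic == pytest.approx(base)
        assert chi2_independence(t.T).statistic == pytest.approx(base)


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        res = kruskal_wallis([[3, 3], [3, 3], [3, 3]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_groups_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(1, 1, size=9)
        res = kruskal_wallis([a, b])
        ref = sps.kruskal(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_ties_match_scipy(self):
        a = [1, 2, 2, 3]
        b = [2, 3, 3, 4]
        c = [1, 1, 4, 4]
        res = kruskal_wallis([a, b, c])
        ref = sps.kruskal(a, b, c)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            groups = [rng.normal(size=10) for _ in range(3)]
            if kruskal_wallis(groups).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / reps < 0.07

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestRankCorrelations:
    def test_spearman_monotone_is_one(self):
        x = np.arange(1, 11, dtype=float)
        assert spearman_rho(x, x**3) == pytest.approx(1.0)

    def test_spearman_reversed_is_minus_one(self):
        x = np.arange(10, dtype=float)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_spearman_ties_vs_hand_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.0, 4.0, 4.0, 1.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ry = np.array([2.5, 2.5, 4.5, 4.5, 1.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_kendall_identical_and_reversed(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, -x) == pytest.approx(-1.0)

    def test_kendall_ties_vs_scipy_tau_b(self):
        x = np.array([1, 2, 2, 3, 4, 4, 5], float)
        y = np.array([2, 1, 3, 3, 5, 4, 4], float)
        assert kendall_tau(x, y) == pytest.approx(sps.kendalltau(x, y).statistic, rel=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y), abs=1e-12)
        assert kendall_tau(x, y**3) == pytest.approx(kendall_tau(x, y), abs=1e-12)

    def test_kendall_test_sign(self):
        x = np.arange(15, dtype=float)
        res = kendall_tau_test(x, x + np.random.default_rng(1).normal(0, 0.1, 15))
        assert res.statistic > 0.9
        assert res.p_value < 0.001


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(1.0, 9.0)
        fit = linear_fit(2 * x, x)
        assert fit.coefficients[1] == pytest.approx(2.0)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_recovery_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10_000)
        y = 1 + 0.5 * x + rng.normal(size=10_000)
        fit = linear_fit(y, x)
        assert abs(fit.coefficients[1] - 0.5) < 3 * fit.standard_errors[1]

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        design = np.column_stack([np.ones(30), X])
        beta_oracle = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(linear_fit(y, X).coefficients, beta_oracle, atol=1e-10)

    def test_binary_predictor_reproduces_t_test(self):
        rng = np.random.default_rng(6)
        g = np.repeat([0.0, 1.0], 12)
        y = rng.normal(size=24) + g
        fit = linear_fit(y, g)
        ref = sps.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert fit.p_values[1] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(400):
            x = rng.normal(size=20)
            y = rng.permutation(x) + rng.normal(size=20)
            pvals.append(linear_fit(y, x).p_values[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.001

    def test_rank_deficiency_names_column(self):
        x = np.ones((10, 1))  # collinear with intercept
        with pytest.raises(ValueError, match="column 0"):
            linear_fit(np.arange(10.0), x)


class TestLogisticFit:
    def test_null_slope_small(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=4000)
        y = rng.binomial(1, 0.5, 4000).astype(float)
        fit = logistic_fit(y, x)
        assert abs(fit.wald_stats[1]) < 4
        assert fit.converged

    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(-1 + x)))
        y = rng.binomial(1, p).astype(float)
        fit = logistic_fit(y, x)
        assert abs(fit.coefficients[1] - 1.0) < 3 * fit.standard_errors[1]

    def test_matches_likelihood_grid_search(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        y = rng.binomial(1, 1 / (1 + np.exp(-0.7 * x))).astype(float)
        fit = logistic_fit(y, x)

        def nll(b0, b1):
            eta = b0 + b1 * x
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        # coarse-to-fine grid around the IRLS optimum's neighbourhood
        b0s = np.linspace(-2, 2, 81)
        b1s = np.linspace(-2, 3, 101)
        grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        b0s = np.linspace(b0s[i] - 0.1, b0s[i] + 0.1, 201)
        b1s = np.linspace(b1s[j] - 0.1, b1s[j] + 0.1, 201)
        grid = np.array([[nll(a, b) for b in b1s] for a in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        assert fit.coefficients[0] == pytest.approx(b0s[i], abs=1e-3)
        assert fit.coefficients[1] == pytest.approx(b1s[j], abs=1e-3)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            logistic_fit(np.ones(10), np.arange(10.0))

    def test_complete_separation_flagged(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        fit = logistic_fit(y, x)
        assert not fit.converged


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Full enumeration over heterozygote counts using exact integers."""
    from fractions import Fraction
    from math import factorial

    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    probs = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        minor_hom = (n_minor - het) // 2
        major_hom = n - het - minor_hom
        num = (
            factorial(n)
            // (factorial(het) * factorial(minor_hom) * factorial(major_hom))
            * 2**het
            * factorial(n_minor)
            * factorial(2 * n - n_minor)
        )
        probs[het] = Fraction(num, factorial(2 * n))
    total = float(sum(probs.values()))
    obs = probs[n_Aa]
    p = float(sum(p for p in probs.values() if p <= obs))
    return p, total


class TestHWEExact:
    def test_monomorphic(self):
        assert hwe_exact(0, 0, 50).p_value == 1.0
        assert hwe_exact(50, 0, 0).p_value == 1.0

    @pytest.mark.parametrize("counts", [(25, 50, 25), (10, 5, 3), (40, 12, 1), (7, 20, 7)])
    def test_matches_enumeration_oracle(self, counts):
        expected, total = hwe_enumeration_oracle(*counts)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert hwe_exact(*counts).p_value == pytest.approx(expected, rel=1e-9)

    def test_all_heterozygotes_significant(self):
        assert hwe_exact(0, 60, 0).p_value < 0.05

    def test_configuration_probabilities_sum_to_one(self):
        # internal consistency: oracle normalization constant is 1
        _, total = hwe_enumeration_oracle(12, 30, 18)
        assert total == pytest.approx(1.0, abs=1e-9)


class TestFixedEffectMeta:
    def test_single_study_identity(self):
        res = fixed_effect_meta([0.3], [0.1])
        assert res.pooled_beta == pytest.approx(0.3)
        assert res.pooled_se == pytest.approx(0.1)

    def test_two_identical_studies(self):
        res = fixed_effect_meta([1.0, 1.0], [1.0, 1.0])
        assert res.pooled_beta == pytest.approx(1.0)
        assert res.pooled_se == pytest.approx(1 / np.sqrt(2))

    def test_heterogeneous_matches_hand_computation(self):
        betas = np.array([0.2, -0.1, 0.5])
        ses = np.array([0.1, 0.2, 0.4])
        w = 1 / ses**2
        res = fixed_effect_meta(betas, ses)
        assert res.pooled_beta == pytest.approx(float((w * betas).sum() / w.sum()), abs=1e-12)
        assert res.pooled_se == pytest.approx(float(1 / np.sqrt(w.sum())), abs=1e-12)
        assert res.study_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.pooled_se <= ses.min()

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            fixed_effect_meta([1.0], [0.0])
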