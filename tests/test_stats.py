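import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from germkin.stats import (
    chi2_homogeneity,
    exact_binomial_ci,
    fisher_exact_2x2,
    kruskal_wallis,
    ols_fit,
)


class TestExactBinomialCI:
    def test_boundary_closed_forms(self):
        lo, hi = exact_binomial_ci(0, 10, 0.90)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.05 ** (1 / 10), abs=1e-12)
        lo1, hi1 = exact_binomial_ci(10, 10, 0.90)
        assert hi1 == 1.0
        assert lo1 == pytest.approx(1 - hi, abs=1e-12)

    def test_symmetric_about_half_at_central_k(self):
        lo, hi = exact_binomial_ci(5, 10, 0.90)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)
        assert 0 < lo < 0.5 < hi < 1

    def test_never_zero_width(self):
        for k, n in [(0, 5), (5, 5), (3, 7)]:
            lo, hi = exact_binomial_ci(k, n, 0.90)
            assert hi - lo > 0

    def test_duality_with_exact_binomial_test(self):
        """p lies in the interval iff neither exact tail falls below alpha/2."""
        level = 0.90
        for k, n in [(0, 12), (3, 12), (7, 20), (20, 20)]:
            lo, hi = exact_binomial_ci(k, n, level)
            for p in np.linspace(0.01, 0.99, 49):
                inside = lo <= p <= hi
                upper_tail = sps.binom.sf(k - 1, n, p)  # P(X >= k)
                lower_tail = sps.binom.cdf(k, n, p)  # P(X <= k)
                accepts = upper_tail >= 0.05 - 1e-12 and lower_tail >= 0.05 - 1e-12
                assert inside == accepts, (k, n, p)

    @pytest.mark.parametrize("k,n,level", [(-1, 10, 0.9), (11, 10, 0.9), (2, 0, 0.9), (2, 10, 1.0)])
    def test_invalid_inputs(self, k, n, level):
        with pytest.raises(ValueError):
            exact_binomial_ci(k, n, level)


def fisher_oracle(k1, n1, k2, n2):
    """Exact-rational enumeration of the two-sided Fisher p-value."""
    big_n, big_k, n_draw = n1 + n2, k1 + k2, n1

    def pmf(j):
        if j < 0 or j > n_draw or big_k - j < 0 or big_k - j > n2:
            return Fraction(0)
        return Fraction(math.comb(big_k, j) * math.comb(big_n - big_k, n_draw - j),
                        math.comb(big_n, n_draw))

    observed = pmf(k1)
    cutoff = observed + observed / 10**7  # guard float ties as the standard convention does
    return float(sum(pmf(j) for j in range(n_draw + 1) if pmf(j) <= cutoff))


class TestFisherExact:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(5, 10, 5, 10).p_value == pytest.approx(1.0)

    def test_total_separation(self):
        res = fisher_exact_2x2(10, 10, 0, 10)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_matches_hypergeometric_enumeration(self):
        for n1, n2 in itertools.product(range(1, 12), repeat=2):
            if n1 + n2 > 12:
                continue
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    got = fisher_exact_2x2(k1, n1, k2, n2).p_value
                    want = fisher_oracle(k1, n1, k2, n2)
                    assert got == pytest.approx(want, abs=1e-9), (k1, n1, k2, n2)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


def kw_permutation_oracle(group1, group2):
    """Two-group exact permutation p via an independent H computation per split."""
    pooled = list(group1) + list(group2)
    n1 = len(group1)
    h_obs = _kw_stat(group1, group2)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if _kw_stat(a, b) >= h_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def _kw_stat(a, b):
    if all(v == a[0] for v in list(a) + list(b)):
        return 0.0
    h, _ = sps.kruskal(a, b)
    return h


class TestKruskalWallis:
    def test_textbook_statistic(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2

    def test_all_tied_degenerate(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize(
        "g1, g2",
        [
            ([1, 3, 5, 7], [2, 4, 6]),
            ([1, 2, 2, 4], [2, 3, 3]),  # heavy ties, as hourly data produce
            ([10, 12], [11, 13, 30, 31, 32]),
        ],
    )
    def test_exact_permutation_p_matches_enumeration(self, g1, g2):
        res = kruskal_wallis([g1, g2], method="exact")
        assert res.exact
        assert res.p_value == pytest.approx(kw_permutation_oracle(g1, g2), abs=1e-12)

    def test_exact_statistic_matches_asymptotic_statistic(self):
        groups = [[1, 2, 2, 4], [2, 3, 3], [1, 4]]
        assert kruskal_wallis(groups, method="exact").statistic == pytest.approx(
            kruskal_wallis(groups).statistic, abs=1e-12
        )

    def test_tie_correction_inflates_h(self):
        tied = [[1, 2, 2], [2, 3, 3]]
        ranks = sps.rankdata([v for g in tied for v in g])
        n = len(ranks)
        raw = 12 / (n * (n + 1)) * (ranks[:3].sum() ** 2 / 3 + ranks[3:].sum() ** 2 / 3) - 3 * (n + 1)
        assert kruskal_wallis(tied).statistic >= raw

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestChi2Homogeneity:
    def test_equal_proportions_are_null(self):
        res = chi2_homogeneity([5, 10, 15], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_hand_computation(self):
        # pooled p = 0.5, expected 5 per cell: chi2 = 4 * 16/5 = 12.8
        res = chi2_homogeneity([9, 1], [10, 10])
        assert res.statistic == pytest.approx(12.8, abs=1e-12)
        assert res.df == 1

    def test_relabeling_invariance(self):
        a = chi2_homogeneity([3, 7, 5], [12, 14, 9]).statistic
        b = chi2_homogeneity([5, 3, 7], [9, 12, 14]).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_or_none_germinated_is_degenerate(self):
        assert chi2_homogeneity([10, 20], [10, 20]).p_value == 1.0
        assert chi2_homogeneity([0, 0], [10, 20]).p_value == 1.0

    def test_zero_seed_group_rejected(self):
        with pytest.raises(ValueError):
            chi2_homogeneity([0, 1], [0, 10])


def ols_oracle(y, x):
    """Normal equations in exact rational arithmetic."""
    y = [Fraction(v) for v in y]
    x = [Fraction(v) for v in x]
    n = len(y)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    beta = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    alpha = (sy - beta * sx) / n
    ybar = sy / n
    sst = sum((v - ybar) ** 2 for v in y)
    ssr = sum((yi - alpha - beta * xi) ** 2 for xi, yi in zip(x, y))
    r2 = 1 - ssr / sst if sst else Fraction(1)
    return float(alpha), float(beta), float(r2)


class TestOLS:
    def test_exact_line_recovery(self):
        x = np.arange(10.0)
        res = ols_fit(2 + 3 * x, x)
        assert res.alpha_hat == pytest.approx(2.0, abs=1e-10)
        assert res.beta_hat == pytest.approx(3.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_hand_normal_equations(self):
        res = ols_fit([0, 1, 3], [0, 1, 2])
        assert res.beta_hat == pytest.approx(1.5, abs=1e-12)
        assert res.alpha_hat == pytest.approx(-1 / 6, abs=1e-12)

    @pytest.mark.parametrize(
        "y, x",
        [
            ([3, 1, 4, 1, 5, 9], [2, 7, 1, 8, 2, 8]),
            ([0, 1, 3, 6], [0, 1, 2, 3]),
            ([10, 8, 13, 9, 11], [4, 5, 6, 7, 8]),
        ],
    )
    def test_matches_rational_arithmetic_oracle(self, y, x):
        alpha, beta, r2 = ols_oracle(y, x)
        res = ols_fit(y, x)
        assert res.alpha_hat == pytest.approx(alpha, abs=1e-10)
        assert res.beta_hat == pytest.approx(beta, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_interval_and_pvalue_conventions(self):
        rng = np.random.default_rng(7)
        x = np.linspace(5, 24, 40)
        y = 33 + 0.7 * x + rng.normal(0, 2, 40)
        res = ols_fit(y, x, level=0.90)
        assert res.ci_beta[0] < res.beta_hat < res.ci_beta[1]
        half = res.ci_beta[1] - res.beta_hat
        t_crit = sps.t.ppf(0.95, len(x) - 2)
        assert half == pytest.approx(t_crit * res.se_beta, rel=1e-9)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1, 2, 3], [4, 4, 4])
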