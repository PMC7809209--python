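"""Statistical primitives for germination proportions and time metrics.

Germination proportions near 0% or 100% are badly served by the normal
approximation (a z-interval collapses to zero width at the boundaries), so
proportion inference here is exact: Clopper-Pearson intervals and Fisher's
exact 2x2 test.  Time metrics (t50, U80-20) are compared across groups with
the rank-based Kruskal-Wallis test, which tolerates the heavy ties produced
by hourly sampling.  Seed-density effects are quantified by ordinary least
squares.  Default confidence level is 90% throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RegressionResult",
    "exact_binomial_ci",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "chi2_homogeneity",
    "ols_fit",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test: str
    df: int | None = None
    exact: bool = False
    group_sizes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression y = alpha + beta*x + noise, with t-based inference."""

    alpha_hat: float
    beta_hat: float
    se_alpha: float
    se_beta: float
    p_alpha: float
    p_beta: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    r_squared: float
    n: int
    level: float


def exact_binomial_ci(k: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Two-sided Clopper-Pearson interval for a binomial proportion.

    Uses Beta quantiles with alpha/2 mass in each tail.  The lower bound is
    exactly 0 when k = 0 and the upper bound exactly 1 when k = n; for finite
    n the interval never has zero width.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k = {k} outside [0, {n}]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def fisher_exact_2x2(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided Fisher exact test comparing proportions k1/n1 and k2/n2.

    The p-value sums the hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed that of the observed table.
    """
    for k, n, name in ((k1, n1, "1"), (k2, n2, "2")):
        if n < 0 or not 0 <= k <= n:
            raise ValueError(f"invalid counts for group {name}: {k}/{n}")
    if n1 + n2 == 0:
        raise ValueError("degenerate 2x2 table: no observations")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        test="fisher_exact",
        exact=True,
        group_sizes=(n1, n2),
    )


def _kw_h(ranks: list[np.ndarray], n_total: int, tie_denom: float) -> float:
    h = 12.0 / (n_total * (n_total + 1)) * sum(r.sum() ** 2 / len(r) for r in ranks)
    h -= 3.0 * (n_total + 1)
    return h / tie_denom


def kruskal_wallis(groups: list[list[float]], method: str = "asymptotic") -> TestResult:
    """Tie-corrected Kruskal-Wallis rank test across >= 2 groups.

    ``method='asymptotic'`` (default) takes the p-value from the chi-square
    distribution with (#groups - 1) df.  ``method='exact'`` enumerates every
    partition of the pooled observations into groups of the observed sizes
    (feasible up to ~10 observations) and reports the fraction of partitions
    with H at least as large as observed.  If every value is tied the test is
    degenerate: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    sizes = tuple(len(a) for a in arrays)
    n_total = sum(sizes)
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", df=len(groups) - 1, group_sizes=sizes)

    df = len(groups) - 1
    if method == "asymptotic":
        h, p = sps.kruskal(*arrays)
        return TestResult(float(h), float(p), "kruskal_wallis", df=df, group_sizes=sizes)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_denom = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    bounds = np.cumsum((0,) + sizes)
    h_obs = _kw_h([ranks[bounds[i] : bounds[i + 1]] for i in range(len(sizes))], n_total, tie_denom)

    n_ge = 0
    n_all = 0
    for assignment in _partitions(tuple(range(n_total)), sizes):
        h = _kw_h([ranks[list(idx)] for idx in assignment], n_total, tie_denom)
        n_all += 1
        if h >= h_obs - 1e-12:
            n_ge += 1
    return TestResult(
        float(h_obs), n_ge / n_all, "kruskal_wallis", df=df, exact=True, group_sizes=sizes
    )


def _partitions(indices: tuple[int, ...], sizes: tuple[int, ...]):
    """All ordered partitions of ``indices`` into blocks of the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    rest_sizes = sizes[1:]
    for block in itertools.combinations(indices, sizes[0]):
        remaining = tuple(i for i in indices if i not in block)
        for rest in _partitions(remaining, rest_sizes):
            yield (block,) + rest


def chi2_homogeneity(germinated: list[int], totals: list[int]) -> TestResult:
    """Pearson chi-square test that germination proportions are equal across groups.

    Operates on the (group x {germinated, not germinated}) count table with
    #groups - 1 degrees of freedom.  When all seeds germinated (or none did)
    the proportions are trivially identical: statistic 0, p = 1.
    """
    if len(germinated) != len(totals) or len(totals) < 2:
        raise ValueError("need germinated/total counts for at least two groups")
    g = np.asarray(germinated, dtype=int)
    n = np.asarray(totals, dtype=int)
    if np.any(n <= 0):
        raise ValueError("every group must contain at least one seed")
    if np.any(g < 0) or np.any(g > n):
        raise ValueError("germinated counts must lie in [0, total]")
    df = len(totals) - 1
    if g.sum() == 0 or g.sum() == n.sum():
        return TestResult(0.0, 1.0, "chi2_homogeneity", df=df, group_sizes=tuple(n))
    table = np.column_stack([g, n - g])
    res = sps.chi2_contingency(table, correction=False)
    return TestResult(
        float(res.statistic), float(res.pvalue), "chi2_homogeneity", df=df, group_sizes=tuple(n)
    )


def ols_fit(y, x, level: float = 0.90) -> RegressionResult:
    """Ordinary least squares of y on a single regressor with an intercept.

    Standard errors come from the unbiased residual variance (n - 2 df);
    p-values are two-sided t tests of alpha = 0 and beta = 0; confidence
    intervals are symmetric t intervals at ``level``.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-d arrays of equal length")
    if len(y) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; slope is not identifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=1 - level)
    return RegressionResult(
        alpha_hat=float(model.params[0]),
        beta_hat=float(model.params[1]),
        se_alpha=float(model.bse[0]),
        se_beta=float(model.bse[1]),
        p_alpha=float(model.pvalues[0]),
        p_beta=float(model.pvalues[1]),
        ci_alpha=(float(ci[0][0]), float(ci[0][1])),
        ci_beta=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(model.rsquared),
        n=int(model.nobs),
        level=level,
    )
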