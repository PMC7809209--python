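"""Layout-bias and seed-density diagnostics for plate germination assays.

Random pipetting of seed suspensions raises two QC questions: does a well's
position on the plate (edge vs interior) bias its germination, and does the
random number of seeds per well shift the kinetics?  This module implements
the corresponding test battery:

* ``edge_effect_tests`` — a 3 x 3 battery: each metric (t50, U80-20, Gmax)
  against each geometric grouping (ring, row, column).  Time metrics are
  compared across groups with Kruskal-Wallis on per-well values; Gmax with a
  chi-square homogeneity test on pooled germinated/total seed counts per
  group (a rank test on per-well proportions is available as a switch).
* ``seed_count_regressions`` — OLS of each index (Gmax, t20, t50, t80) on
  the per-well seed count s.
* ``conditional_means_by_count`` — mean of an index conditionally on s, with
  t-based CIs for time metrics and exact binomial CIs for Gmax.

Wells from all plates are pooled into one population by default.  Wells with
fewer than ``min_germinated`` germinated seeds are excluded from time-metric
tests and regressions but kept for Gmax.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinetics import metrics_table
from .plate import PlateExperiment
from .stats import RegressionResult, chi2_homogeneity, exact_binomial_ci, kruskal_wallis, ols_fit

__all__ = [
    "edge_effect_tests",
    "seed_count_regressions",
    "regression_frame",
    "conditional_means_by_count",
]

EDGE_METRICS = ("t50", "u_80_20", "g_max")
EDGE_GROUPINGS = ("ring", "row", "column")


def edge_effect_tests(
    experiments: Iterable[PlateExperiment],
    min_germinated: int = 3,
    mode: str = "relative",
    gmax_test: str = "chi2",
) -> pd.DataFrame:
    """Run the nine position-effect tests; one row per (metric, grouping).

    Columns: metric, grouping, test, statistic, p_value, n_wells, n_seeds,
    n_groups, note.  A grouping with fewer than two nonempty groups is
    flagged untestable (NaN statistic/p) rather than raising.
    """
    table = metrics_table(experiments, min_germinated=min_germinated, mode=mode)
    rows = []
    for metric in EDGE_METRICS:
        for grouping in EDGE_GROUPINGS:
            rows.append(_one_edge_test(table, metric, grouping, gmax_test))
    return pd.DataFrame(rows)


def _one_edge_test(table: pd.DataFrame, metric: str, grouping: str, gmax_test: str) -> dict:
    out = {"metric": metric, "grouping": grouping, "note": ""}
    if metric == "g_max" and gmax_test == "chi2":
        used = table
        agg = used.groupby(grouping)[["n_germinated", "n_seeds"]].sum()
        agg = agg[agg["n_seeds"] > 0]
        out["test"] = "chi2_homogeneity"
        if len(agg) < 2:
            return _untestable(out, used)
        res = chi2_homogeneity(list(agg["n_germinated"]), list(agg["n_seeds"]))
    else:
        if metric == "g_max":
            used = table
            out["test"] = "kruskal_wallis"
        else:
            used = table[table["eligible"] & table[metric].notna()]
            out["test"] = "kruskal_wallis"
        groups = [g[metric].to_numpy(dtype=float) for _, g in used.groupby(grouping) if len(g)]
        if len(groups) < 2:
            return _untestable(out, used)
        res = kruskal_wallis(groups)
    out.update(
        statistic=res.statistic,
        p_value=res.p_value,
        n_wells=int(len(used)),
        n_seeds=int(used["n_seeds"].sum()),
        n_groups=len(res.group_sizes),
    )
    return out


def _untestable(out: dict, used: pd.DataFrame) -> dict:
    out.update(
        statistic=float("nan"),
        p_value=float("nan"),
        n_wells=int(len(used)),
        n_seeds=int(used["n_seeds"].sum()),
        n_groups=0,
        note="untestable: fewer than two nonempty groups",
    )
    return out


REGRESSION_METRICS = ("g_max", "t20", "t50", "t80")


def seed_count_regressions(
    experiments: Iterable[PlateExperiment],
    min_germinated: int = 3,
    level: float = 0.90,
    mode: str = "relative",
) -> dict[str, RegressionResult]:
    """OLS of each kinetic index on the per-well seed count s.

    Gmax (as a proportion) is regressed over all wells; t20/t50/t80 over
    eligible wells only.  Returns one RegressionResult per metric.
    """
    table = metrics_table(experiments, min_germinated=min_germinated, mode=mode)
    out: dict[str, RegressionResult] = {}
    for metric in REGRESSION_METRICS:
        used = table if metric == "g_max" else table[table["eligible"] & table[metric].notna()]
        out[metric] = ols_fit(
            used[metric].to_numpy(dtype=float),
            used["n_seeds"].to_numpy(dtype=float),
            level=level,
        )
    return out


def regression_frame(results: dict[str, RegressionResult]) -> pd.DataFrame:
    """Flatten regression results into a four-row report table."""
    rows = []
    for metric, r in results.items():
        rows.append(
            {
                "metric": metric,
                "alpha_hat": r.alpha_hat,
                "se_alpha": r.se_alpha,
                "p_alpha": r.p_alpha,
                "ci_alpha_low": r.ci_alpha[0],
                "ci_alpha_high": r.ci_alpha[1],
                "beta_hat": r.beta_hat,
                "se_beta": r.se_beta,
                "p_beta": r.p_beta,
                "ci_beta_low": r.ci_beta[0],
                "ci_beta_high": r.ci_beta[1],
                "r_squared": r.r_squared,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def conditional_means_by_count(
    experiments: Iterable[PlateExperiment],
    metric: str,
    level: float = 0.90,
    min_germinated: int = 3,
    mode: str = "relative",
) -> pd.DataFrame:
    """Mean of ``metric`` conditionally on the per-well seed count.

    For time metrics the CI is Gaussian: mean +/- t-quantile * s / sqrt(n)
    with n - 1 df, undefined when a count is represented by a single well.
    For ``g_max`` the estimate pools seeds across the wells of each count
    and the CI is the exact binomial interval.
    """
    if metric not in ("g_max",) + tuple(m for m in REGRESSION_METRICS if m != "g_max") + ("u_80_20",):
        raise ValueError(f"unknown metric {metric!r}")
    table = metrics_table(experiments, min_germinated=min_germinated, mode=mode)
    rows = []
    for s, grp in table.groupby("n_seeds"):
        if metric == "g_max":
            k = int(grp["n_germinated"].sum())
            n = int(grp["n_seeds"].sum())
            lo, hi = exact_binomial_ci(k, n, level)
            rows.append(
                {"n_seeds": int(s), "n_wells": len(grp), "mean": k / n, "lower": lo, "upper": hi}
            )
        else:
            vals = grp.loc[grp["eligible"] & grp[metric].notna(), metric].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            mean = float(vals.mean())
            if len(vals) > 1:
                half = sps.t.ppf((1 + level) / 2, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
                lo, hi = mean - half, mean + half
            else:
                lo = hi = float("nan")
            rows.append(
                {"n_seeds": int(s), "n_wells": len(vals), "mean": mean, "lower": lo, "upper": hi}
            )
    return pd.DataFrame(rows)
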