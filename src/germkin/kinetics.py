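"""Cumulative germination curves and per-well kinetic metrics.

From the per-seed event hours of a well we derive the standard germination
indices:

* ``Gmax`` — final fraction of germinated seeds among seeds sown;
* ``t20 / t50 / t80`` — first sampled hour at which cumulative germination
  reaches 20/50/80% of a denominator.  *Relative* metrics use the seeds that
  eventually germinated as denominator; *absolute* metrics use all seeds
  sown.  Relative is the default;
* ``U80-20`` — uniformity, the interval t80 - t20 (smaller = more
  synchronous germination).

Because observation is hourly, quantiles follow a step rule with no
interpolation: t_x is the hour of the ceil(x% * denominator)-th germination
event.  A single germinated seed therefore defines all quantiles at once
(t20 = t50 = t80).  Wells with fewer than ``min_germinated`` events (default
3, "more than 2 germinated seeds") have their time metrics marked undefined.

Condition-level curves pool seeds across wells: the estimate at each hour is
total germinated over total sown — equivalent to weighting wells by seed
number, which is the right estimator when the per-well seed count is itself
random — with exact Clopper-Pearson bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate import PlateExperiment, SeedRecord, WellObservation, group_label, ring_of
from .stats import exact_binomial_ci

__all__ = [
    "GerminationCurve",
    "KineticMetrics",
    "cumulative_curve",
    "pooled_curve",
    "t_relative",
    "t_absolute",
    "well_metrics",
    "metrics_table",
    "summarize_condition",
    "condition_summary",
]


@dataclass
class GerminationCurve:
    """Step function of cumulative germinated counts on the sampling grid."""

    times: np.ndarray
    counts: np.ndarray
    n: int
    level: float | None = None
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"hour": self.times, "germinated": self.counts, "total": self.n,
             "proportion": self.proportions}
        )
        if self.lower is not None:
            df["lower"] = self.lower
            df["upper"] = self.upper
        return df


@dataclass
class KineticMetrics:
    """Per-well germination indices; time metrics are None when undefined."""

    n_seeds: int
    n_germinated: int
    g_max: float
    t20: float | None
    t50: float | None
    t80: float | None
    t20_abs: float | None
    t50_abs: float | None
    t80_abs: float | None
    u_80_20: float | None
    eligible: bool
    mode: str = "relative"


def _event_hours(seeds: Iterable[SeedRecord]) -> list[float]:
    return sorted(s.event_hour for s in seeds if s.germinated)


def _time_grid(dt: float, censor_hour: float) -> np.ndarray:
    n_steps = int(round(censor_hour / dt))
    return np.arange(0, n_steps + 1) * dt


def cumulative_curve(
    seeds: Sequence[SeedRecord], dt: float = 1.0, censor_hour: float = 120.0
) -> GerminationCurve:
    """Count, at each grid hour, the seeds whose event hour has passed."""
    times = _time_grid(dt, censor_hour)
    events = np.asarray(_event_hours(seeds), dtype=float)
    counts = np.searchsorted(events, times, side="right")
    return GerminationCurve(times=times, counts=counts, n=len(seeds))


def pooled_curve(
    wells: Sequence[WellObservation],
    dt: float = 1.0,
    censor_hour: float = 120.0,
    level: float = 0.90,
) -> GerminationCurve:
    """Seed-count-weighted germination curve over wells, with exact CI bands.

    The estimate at hour t is (total seeds germinated by t) / (total seeds
    sown); the band is the two-sided Clopper-Pearson interval at ``level``
    for that binomial count.
    """
    if not wells:
        raise ValueError("pooled_curve needs at least one well")
    times = _time_grid(dt, censor_hour)
    events = np.asarray(sorted(h for w in wells for h in w.event_hours), dtype=float)
    counts = np.searchsorted(events, times, side="right")
    n_total = sum(w.n_seeds for w in wells)
    bounds = np.array([exact_binomial_ci(int(k), n_total, level) for k in counts])
    return GerminationCurve(
        times=times, counts=counts, n=n_total,
        level=level, lower=bounds[:, 0], upper=bounds[:, 1],
    )


def _quantile_hour(x: float, events: Sequence[float], denominator: int) -> float | None:
    if not 0 < x <= 100:
        raise ValueError(f"percentage x = {x} outside (0, 100]")
    if denominator == 0:
        return None
    # exact threshold arithmetic: ceil(x/100 * denominator) without float fuzz
    threshold = math.ceil(Fraction(str(x)) * denominator / 100)
    if len(events) < threshold:
        return None
    return events[threshold - 1]


def t_relative(x: float, seeds: Sequence[SeedRecord]) -> float | None:
    """First hour at which cumulative germination reaches x% of the seeds
    that eventually germinated; None when no seed germinated."""
    events = _event_hours(seeds)
    return _quantile_hour(x, events, len(events))


def t_absolute(x: float, seeds: Sequence[SeedRecord], n: int | None = None) -> float | None:
    """First hour at which cumulative germination reaches x% of all seeds
    sown; None when that level is never attained."""
    seeds = list(seeds)
    events = _event_hours(seeds)
    return _quantile_hour(x, events, len(seeds) if n is None else n)


def well_metrics(
    well: WellObservation, min_germinated: int = 3, mode: str = "relative"
) -> KineticMetrics:
    """Extract the kinetic indices of one well.

    ``g_max`` is always computed.  The time metrics (and U80-20) are computed
    only when the well has at least ``min_germinated`` germinated seeds;
    otherwise they are None and the well is flagged ineligible, mirroring the
    "more than 2 germinated seeds" filter used for summary tables.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown mode {mode!r}")
    n = well.n_seeds
    events = well.event_hours
    g = len(events)
    eligible = g >= min_germinated

    t_abs = {x: _quantile_hour(x, events, n) for x in (20, 50, 80)}
    if eligible:
        t_rel = {x: _quantile_hour(x, events, g) for x in (20, 50, 80)}
        chosen = t_rel if mode == "relative" else t_abs
        t20, t50, t80 = chosen[20], chosen[50], chosen[80]
        u = t80 - t20 if (t20 is not None and t80 is not None) else None
    else:
        t20 = t50 = t80 = u = None

    return KineticMetrics(
        n_seeds=n,
        n_germinated=g,
        g_max=g / n,
        t20=t20,
        t50=t50,
        t80=t80,
        t20_abs=t_abs[20] if eligible else None,
        t50_abs=t_abs[50] if eligible else None,
        t80_abs=t_abs[80] if eligible else None,
        u_80_20=u,
        eligible=eligible,
        mode=mode,
    )


def metrics_table(
    experiments: Iterable[PlateExperiment],
    min_germinated: int = 3,
    mode: str = "relative",
) -> pd.DataFrame:
    """Tidy per-well metrics across experiments (one row per well).

    Includes the plate-geometry groupings (row, column, ring) so layout
    diagnostics can run directly on this table.
    """
    rows = []
    for exp in experiments:
        for well in exp.wells:
            m = well_metrics(well, min_germinated=min_germinated, mode=mode)
            rows.append(
                {
                    "plate_id": exp.plate_id,
                    "well": well.position.label,
                    "row": well.position.row_label,
                    "column": well.position.column,
                    "ring": ring_of(well.position, exp.n_rows, exp.n_cols),
                    "genotype": well.genotype,
                    "compound": well.compound,
                    "dose_uM": well.dose_um,
                    "n_seeds": m.n_seeds,
                    "n_germinated": m.n_germinated,
                    "g_max": m.g_max,
                    "t20": m.t20,
                    "t50": m.t50,
                    "t80": m.t80,
                    "u_80_20": m.u_80_20,
                    "eligible": m.eligible,
                }
            )
    return pd.DataFrame(rows)


def summarize_condition(
    wells: Sequence[WellObservation], min_germinated: int = 3, mode: str = "relative"
) -> dict:
    """Mean (sd) of each index over one condition's wells.

    ``g_max`` statistics use all wells (plain well mean; the seed-weighted
    pooled estimate is reported alongside); time metrics average only the
    eligible wells, so the linear identity mean(U80-20) = mean(t80) -
    mean(t20) holds by construction.  Standard deviations are population
    style (ddof = 0).  Cells with no eligible well are NaN.
    """
    if not wells:
        raise ValueError("summarize_condition needs at least one well")
    ms = [well_metrics(w, min_germinated=min_germinated, mode=mode) for w in wells]
    g_max = np.array([m.g_max for m in ms])
    out = {
        "n_wells": len(ms),
        "g_max_mean": float(g_max.mean()),
        "g_max_sd": float(g_max.std(ddof=0)),
        "g_max_pooled": sum(m.n_germinated for m in ms) / sum(m.n_seeds for m in ms),
    }
    for name in ("t20", "t50", "t80", "u_80_20"):
        vals = np.array([getattr(m, name) for m in ms if getattr(m, name) is not None])
        out[f"{name}_mean"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"{name}_sd"] = float(vals.std(ddof=0)) if len(vals) else float("nan")
        out[f"{name}_n"] = int(len(vals))
    return out


def condition_summary(
    experiments: Iterable[PlateExperiment], min_germinated: int = 3, mode: str = "relative"
) -> pd.DataFrame:
    """Per-(genotype, compound, dose) summary table, one row per condition."""
    by_cond: dict[tuple, list[WellObservation]] = {}
    for exp in experiments:
        for well in exp.wells:
            by_cond.setdefault(well.condition, []).append(well)
    rows = []
    for (genotype, compound, dose), wells in sorted(by_cond.items()):
        row = {"genotype": genotype, "compound": compound, "dose_uM": dose}
        row.update(summarize_condition(wells, min_germinated=min_germinated, mode=mode))
        rows.append(row)
    return pd.DataFrame(rows)
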