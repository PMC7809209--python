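"""Stochastic simulator for plate germination assays.

No public per-seed dataset exists for this kind of assay, so the simulator
is the test bed for the whole pipeline and the engine for power and type-I
studies.  The generative model:

* **Seed count** per well: a Normal(mean 13, sd 4) draw rounded to the
  nearest integer and resampled until it lies in [5, 24] — matching the
  observed pipetted-droplet variability.
* **Viability**: each seed independently germinates (eventually) with
  probability ``v(d) = v0 / (1 + (d / ec50)^hill)``, a Hill-type
  suppression of the maximal germination fraction by inhibitor dose d (uM).
* **Timing**: a germinating seed's event time is log-normal with log-sd
  ``sigma`` and median ``m(d, s) = m0 * (1 + a*d / (d + K)) + beta *
  (s - 13)``: a saturating dose-dependent delay on top of the 33 h water
  median, plus an additive seed-density delay of ``beta`` hours per seed
  away from the mean count (off by default).
* **Observation**: events are recorded at the first sampling-grid hour at
  or after the true time; seeds past the censor hour are non-germinated.
* An optional **spatial effect** adds a time delay or viability change to
  the wells of one geometric group, for power studies of the edge-effect
  battery.

Everything is driven by one seeded numpy Generator; identical (config,
seed) gives byte-identical CSV output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .plate import (
    PlateExperiment,
    SeedRecord,
    Treatment,
    WellObservation,
    WellPosition,
    group_label,
)

__all__ = [
    "SpatialEffect",
    "SimConfig",
    "SimTruth",
    "simulate_plate",
    "simulate_experiment",
    "null_experiment",
]


@dataclass(frozen=True)
class SpatialEffect:
    """Additive distortion applied to one geometric group of wells."""

    scheme: str  # row | column | ring
    group: str | int
    delay_hours: float = 0.0
    viability_delta: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    n_rows: int = 8
    n_cols: int = 12
    n_plates: int = 1
    seed_count_mean: float = 13.0
    seed_count_sd: float = 4.0
    seed_count_min: int = 5
    seed_count_max: int = 24
    viability: float = 0.97  # v0: germination probability in water
    median_hours: float = 33.0  # m0: log-normal median in water
    log_sd: float = 0.10  # sigma of log event time
    ec50_um: float = 1.6  # dose halving the viable fraction
    hill: float = 1.5
    delay_a: float = 1.5  # max relative median delay at saturating dose
    delay_k_um: float = 3.0  # dose of half-maximal delay
    density_effect_beta: float = 0.0  # hours of median shift per seed
    spatial_effect: SpatialEffect | None = None
    censor_hour: float = 120.0
    dt: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.viability <= 1:
            raise ValueError("viability must lie in [0, 1]")
        if self.median_hours <= 0 or self.censor_hour <= 0 or self.dt <= 0:
            raise ValueError("median_hours, censor_hour and dt must be positive")
        if self.seed_count_min < 1 or self.seed_count_max < self.seed_count_min:
            raise ValueError("invalid seed-count bounds")
        if self.log_sd < 0 or self.ec50_um <= 0 or self.hill <= 0 or self.delay_k_um <= 0:
            raise ValueError("invalid time-law or dose-response parameters")

    def viability_at(self, dose_um: float) -> float:
        if dose_um <= 0:
            return self.viability
        return self.viability / (1.0 + (dose_um / self.ec50_um) ** self.hill)

    def median_at(self, dose_um: float, n_seeds: int | float | None = None) -> float:
        m = self.median_hours
        if dose_um > 0:
            m *= 1.0 + self.delay_a * dose_um / (dose_um + self.delay_k_um)
        if n_seeds is not None and self.density_effect_beta:
            # additive per-seed delay: keeps the expected t50 linear in the
            # seed count, so a linear regression targets beta without bias
            m = max(self.dt, m + self.density_effect_beta * (n_seeds - self.seed_count_mean))
        return m


@dataclass
class SimTruth:
    """Per-well generative parameters, for parameter-recovery tests."""

    wells: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.wells, indent=1, sort_keys=True))


def _draw_seed_count(config: SimConfig, rng: np.random.Generator) -> int:
    while True:
        s = int(round(rng.normal(config.seed_count_mean, config.seed_count_sd)))
        if config.seed_count_min <= s <= config.seed_count_max:
            return s


def _well_distortion(config: SimConfig, pos: WellPosition) -> tuple[float, float]:
    eff = config.spatial_effect
    if eff is None:
        return 0.0, 0.0
    label = group_label(pos, eff.scheme, config.n_rows, config.n_cols)
    if label == eff.group:
        return eff.delay_hours, eff.viability_delta
    return 0.0, 0.0


def simulate_plate(
    config: SimConfig,
    plate_map: dict[str, Treatment],
    plate_id: str = "P1",
    rng: np.random.Generator | None = None,
) -> tuple[PlateExperiment, SimTruth]:
    """Simulate one plate under the treatments of ``plate_map``.

    Each mapped well draws its seed count, per-seed viability Bernoullis and
    log-normal event times; events are snapped up to the sampling grid and
    censored at ``config.censor_hour``.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    wells: list[WellObservation] = []
    truth = SimTruth()
    for label in sorted(plate_map, key=lambda s: WellPosition.from_label(s)):
        trt = plate_map[label]
        pos = WellPosition.from_label(label)
        delay, vdelta = _well_distortion(config, pos)
        s = _draw_seed_count(config, rng)
        v = min(1.0, max(0.0, config.viability_at(trt.dose_um) + vdelta))
        median = config.median_at(trt.dose_um, s)
        viable = rng.random(s) < v
        times = median * np.exp(rng.normal(0.0, config.log_sd, size=s)) + delay
        hours = np.ceil(times / config.dt - 1e-9) * config.dt
        seeds = []
        for i in range(s):
            if viable[i] and hours[i] <= config.censor_hour:
                seeds.append(SeedRecord(seed_index=i + 1, germinated=True, event_hour=float(hours[i])))
            else:
                seeds.append(SeedRecord(seed_index=i + 1, germinated=False))
        wells.append(
            WellObservation(
                position=pos, genotype=trt.genotype, compound=trt.compound,
                dose_um=trt.dose_um, seeds=seeds,
            )
        )
        # detection probability of a viable seed: log-normal CDF at the censor
        if delay >= config.censor_hour:
            p_seen = 0.0
        elif config.log_sd > 0:
            p_seen = float(
                sps.norm.cdf(
                    (math.log(config.censor_hour - delay) - math.log(median)) / config.log_sd
                )
            )
        else:
            p_seen = float(median + delay <= config.censor_hour)
        truth.wells[f"{plate_id}:{label}"] = {
            "n_seeds": s,
            "viability": v,
            "median_hours": median + delay,
            "expected_gmax": v * p_seen,
            "dose_uM": trt.dose_um,
        }
    return (
        PlateExperiment(
            plate_id=plate_id, wells=wells, n_rows=config.n_rows, n_cols=config.n_cols,
            sampling_interval=config.dt, censor_hour=config.censor_hour,
        ),
        truth,
    )


def _all_positions(config: SimConfig) -> list[WellPosition]:
    return [
        WellPosition(r, c) for r in range(config.n_rows) for c in range(config.n_cols)
    ]


def simulate_experiment(
    config: SimConfig,
    conditions: Sequence[Treatment],
    wells_per_condition: int = 12,
) -> tuple[list[PlateExperiment], list[dict[str, Treatment]], SimTruth]:
    """Simulate a randomized multi-condition design across one or more plates.

    The design (``len(conditions) * wells_per_condition`` wells) is assigned
    to well positions by a random permutation per plate, filling plates in
    order; it must fit on ``config.n_plates`` plates.  Returns the
    experiments, their plate maps and the pooled generative truth.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    if wells_per_condition < 1:
        raise ValueError("wells_per_condition must be >= 1")
    cells_per_plate = config.n_rows * config.n_cols
    total = len(conditions) * wells_per_condition
    if total > config.n_plates * cells_per_plate:
        raise ValueError(
            f"design of {total} wells exceeds {config.n_plates} plate(s) "
            f"of {cells_per_plate} wells"
        )
    rng = np.random.default_rng(config.rng_seed)
    slots = [trt for trt in conditions for _ in range(wells_per_condition)]
    experiments, maps = [], []
    truth = SimTruth()
    for p in range(config.n_plates):
        batch = slots[p * cells_per_plate : (p + 1) * cells_per_plate]
        if not batch:
            break
        positions = _all_positions(config)
        order = rng.permutation(len(positions))
        plate_map = {
            positions[order[i]].label: trt for i, trt in enumerate(batch)
        }
        plate_id = f"SIM{p + 1}"
        exp, t = simulate_plate(config, plate_map, plate_id=plate_id, rng=rng)
        experiments.append(exp)
        maps.append(plate_map)
        truth.wells.update(t.wells)
    return experiments, maps, truth


def null_experiment(
    config: SimConfig, genotype: str = "Col-0", compound: str = "water"
) -> tuple[list[PlateExperiment], SimTruth]:
    """Full plates of a single untreated condition (the QC null scenario)."""
    trt = Treatment(genotype=genotype, compound=compound, dose_um=0.0)
    cells = config.n_rows * config.n_cols
    exps, _, truth = simulate_experiment(config, [trt], wells_per_condition=cells * config.n_plates)
    return exps, truth
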