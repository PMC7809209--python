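"""Domain model for plate-structured germination data.

A germination assay sows a variable number of seeds into each well of a
microplate (8 rows x 12 columns by default) and images every well at a fixed
sampling interval, recording for each seed the first hour at which radicle
protrusion is visible.  Seeds not seen to germinate by the end of the imaging
window are right-censored.

The on-disk interchange format is a tidy long CSV with one row per seed
(columns: plate_id, well, genotype, compound, dose_uM, seed_index,
germination_hour, censor_hour; an empty germination_hour means censored),
plus a YAML plate map assigning treatments to wells.
"""

from __future__ import annotations

import csv
import logging
import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

ROW_LETTERS = string.ascii_uppercase

__all__ = [
    "WellPosition",
    "SeedRecord",
    "WellObservation",
    "PlateExperiment",
    "Treatment",
    "Violation",
    "ring_of",
    "group_label",
    "read_long_csv",
    "write_long_csv",
    "read_plate_map",
    "validate",
]

CSV_COLUMNS = [
    "plate_id",
    "well",
    "genotype",
    "compound",
    "dose_uM",
    "seed_index",
    "germination_hour",
    "censor_hour",
]


@dataclass(frozen=True, order=True)
class WellPosition:
    """Zero-based (row, col) grid coordinate; canonical label is 'A1'..'H12'."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return f"{ROW_LETTERS[self.row]}{self.col + 1}"

    @property
    def row_label(self) -> str:
        return ROW_LETTERS[self.row]

    @property
    def column(self) -> int:
        """One-based column number as printed on the plate."""
        return self.col + 1

    @classmethod
    def from_label(cls, label: str) -> "WellPosition":
        label = label.strip().upper()
        if len(label) < 2 or label[0] not in ROW_LETTERS or not label[1:].isdigit():
            raise ValueError(f"malformed well label {label!r}")
        return cls(row=ROW_LETTERS.index(label[0]), col=int(label[1:]) - 1)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class SeedRecord:
    """One seed: either a germination hour or a censored (no-event) record."""

    seed_index: int
    germinated: bool
    event_hour: float | None = None

    def __post_init__(self) -> None:
        if self.germinated != (self.event_hour is not None):
            raise ValueError("event_hour must be present iff germinated")
        if self.event_hour is not None and self.event_hour <= 0:
            raise ValueError("event_hour must be positive")


@dataclass
class WellObservation:
    """All seeds observed in one well under one treatment."""

    position: WellPosition
    genotype: str
    compound: str
    dose_um: float
    seeds: list[SeedRecord] = field(default_factory=list)

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def n_germinated(self) -> int:
        return sum(1 for s in self.seeds if s.germinated)

    @property
    def event_hours(self) -> list[float]:
        """Germination hours of germinated seeds, sorted ascending."""
        return sorted(s.event_hour for s in self.seeds if s.germinated)

    @property
    def condition(self) -> tuple[str, str, float]:
        return (self.genotype, self.compound, self.dose_um)


@dataclass
class PlateExperiment:
    """One microplate run: grid geometry, sampling clock and wells."""

    plate_id: str
    wells: list[WellObservation] = field(default_factory=list)
    n_rows: int = 8
    n_cols: int = 12
    sampling_interval: float = 1.0
    censor_hour: float = 120.0

    def well(self, label: str) -> WellObservation:
        pos = WellPosition.from_label(label)
        for w in self.wells:
            if w.position == pos:
                return w
        raise KeyError(f"no well {label} on plate {self.plate_id}")


@dataclass(frozen=True)
class Treatment:
    genotype: str
    compound: str
    dose_um: float


@dataclass(frozen=True)
class Violation:
    plate_id: str
    well: str
    rule: str

    def __str__(self) -> str:
        return f"[{self.plate_id}:{self.well}] {self.rule}"


def ring_of(position: WellPosition, n_rows: int = 8, n_cols: int = 12) -> int:
    """Distance of a well to the closest plate border (border wells = ring 0).

    On an 8x12 plate rings take values 0..3; rings partition the grid and are
    invariant under 180-degree plate rotation.
    """
    r, c = position.row, position.col
    if not 0 <= r < n_rows:
        raise ValueError(f"row {r} off a {n_rows}x{n_cols} grid (well {position.label})")
    if not 0 <= c < n_cols:
        raise ValueError(f"column {c} off a {n_rows}x{n_cols} grid (well {position.label})")
    return min(r, n_rows - 1 - r, c, n_cols - 1 - c)


GROUP_SCHEMES = ("row", "column", "ring")


def group_label(
    position: WellPosition, scheme: str, n_rows: int = 8, n_cols: int = 12
) -> str | int:
    """Group a well by plate geometry: its row letter, column number or ring."""
    if scheme == "row":
        return position.row_label
    if scheme == "column":
        return position.column
    if scheme == "ring":
        return ring_of(position, n_rows, n_cols)
    raise ValueError(f"unknown grouping scheme {scheme!r}; expected one of {GROUP_SCHEMES}")


def _on_time_grid(hour: float, dt: float) -> bool:
    k = hour / dt
    return abs(k - round(k)) < 1e-9 and round(k) >= 1


def read_long_csv(
    path: str | Path,
    n_rows: int = 8,
    n_cols: int = 12,
    sampling_interval: float = 1.0,
) -> list[PlateExperiment]:
    """Parse the long per-seed CSV into validated :class:`PlateExperiment` objects.

    Rows are grouped by (plate_id, well); output ordering is deterministic:
    plates in first-appearance order, wells by grid position, seeds by index.
    """
    path = Path(path)
    plates: dict[str, dict[WellPosition, WellObservation]] = {}
    censor: dict[str, float] = {}
    seen: set[tuple[str, str, int]] = set()

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            plate_id = row["plate_id"]
            pos = WellPosition.from_label(row["well"])
            if not (0 <= pos.row < n_rows and 0 <= pos.col < n_cols):
                raise ValueError(f"{path} line {i}: well {row['well']} off the {n_rows}x{n_cols} grid")
            seed_index = int(row["seed_index"])
            key = (plate_id, pos.label, seed_index)
            if key in seen:
                raise ValueError(f"{path} line {i}: duplicate seed {key}")
            seen.add(key)
            censor_hour = float(row["censor_hour"])
            prev = censor.setdefault(plate_id, censor_hour)
            if prev != censor_hour:
                raise ValueError(f"{path} line {i}: inconsistent censor_hour on plate {plate_id}")
            raw_hour = row["germination_hour"].strip()
            if raw_hour:
                hour = float(raw_hour)
                if hour > censor_hour:
                    raise ValueError(
                        f"{path} line {i}: germination_hour {hour} exceeds censor_hour {censor_hour}"
                    )
                rec = SeedRecord(seed_index=seed_index, germinated=True, event_hour=hour)
            else:
                rec = SeedRecord(seed_index=seed_index, germinated=False)
            wells = plates.setdefault(plate_id, {})
            if pos not in wells:
                wells[pos] = WellObservation(
                    position=pos,
                    genotype=row["genotype"],
                    compound=row["compound"],
                    dose_um=float(row["dose_uM"]),
                )
            wells[pos].seeds.append(rec)

    experiments = []
    for plate_id, wells in plates.items():
        ordered = []
        for pos in sorted(wells):
            w = wells[pos]
            w.seeds.sort(key=lambda s: s.seed_index)
            ordered.append(w)
        experiments.append(
            PlateExperiment(
                plate_id=plate_id,
                wells=ordered,
                n_rows=n_rows,
                n_cols=n_cols,
                sampling_interval=sampling_interval,
                censor_hour=censor[plate_id],
            )
        )
    logger.info("read %d seed rows / %d plates from %s", len(seen), len(experiments), path)
    return experiments


def write_long_csv(experiments: Iterable[PlateExperiment], path: str | Path) -> None:
    """Write experiments in the exact dialect read by :func:`read_long_csv`."""
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for exp in experiments:
            for well in sorted(exp.wells, key=lambda w: w.position):
                for seed in sorted(well.seeds, key=lambda s: s.seed_index):
                    writer.writerow(
                        [
                            exp.plate_id,
                            well.position.label,
                            well.genotype,
                            well.compound,
                            _fmt(well.dose_um),
                            seed.seed_index,
                            _fmt(seed.event_hour) if seed.germinated else "",
                            _fmt(exp.censor_hour),
                        ]
                    )
                    n += 1
    logger.info("wrote %d seed rows to %s", n, path)


def _fmt(x: float) -> str:
    return format(int(x)) if float(x).is_integer() else repr(float(x))


def _expand_wells(entry: Mapping, n_rows: int, n_cols: int) -> list[WellPosition]:
    out: list[WellPosition] = []
    if "wells" in entry:
        out.extend(WellPosition.from_label(w) for w in entry["wells"])
    if "range" in entry:
        lo, _, hi = str(entry["range"]).partition(":")
        a, b = WellPosition.from_label(lo), WellPosition.from_label(hi)
        for r in range(min(a.row, b.row), max(a.row, b.row) + 1):
            for c in range(min(a.col, b.col), max(a.col, b.col) + 1):
                out.append(WellPosition(r, c))
    if not out:
        raise ValueError("plate-map entry declares neither 'wells' nor 'range'")
    for pos in out:
        if not (0 <= pos.row < n_rows and 0 <= pos.col < n_cols):
            raise ValueError(f"plate-map well {pos.label} off the {n_rows}x{n_cols} grid")
    return out


def read_plate_map(
    path: str | Path, n_rows: int = 8, n_cols: int = 12
) -> dict[str, Treatment]:
    """Read a YAML plate map into a well-label -> :class:`Treatment` mapping.

    The map is a list of entries under ``wells:``, each with a treatment
    (genotype, compound, dose_uM) and either an explicit ``wells`` list or a
    rectangular ``range`` such as ``A1:H6``.  A well declared twice is an
    error (overlapping layouts are almost always a transcription mistake).
    """
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    entries = doc.get("wells", [])
    mapping: dict[str, Treatment] = {}
    for entry in entries:
        trt = Treatment(
            genotype=str(entry.get("genotype", "")),
            compound=str(entry.get("compound", "")),
            dose_um=float(entry.get("dose_uM", 0.0)),
        )
        for pos in _expand_wells(entry, n_rows, n_cols):
            if pos.label in mapping:
                raise ValueError(f"well {pos.label} declared more than once in {path}")
            mapping[pos.label] = trt
    logger.info("plate map %s: %d wells", path, len(mapping))
    return mapping


def validate(experiment: PlateExperiment) -> list[Violation]:
    """Check every model invariant; return violations instead of raising."""
    out: list[Violation] = []
    dt = experiment.sampling_interval
    seen_pos: set[WellPosition] = set()
    for well in experiment.wells:
        pos = well.position
        label = pos.label
        if not (0 <= pos.row < experiment.n_rows and 0 <= pos.col < experiment.n_cols):
            out.append(Violation(experiment.plate_id, label, "well position off grid"))
        if pos in seen_pos:
            out.append(Violation(experiment.plate_id, label, "duplicate well position"))
        seen_pos.add(pos)
        if well.n_seeds < 1:
            out.append(Violation(experiment.plate_id, label, "well contains no seeds"))
        indices = [s.seed_index for s in well.seeds]
        if len(set(indices)) != len(indices):
            out.append(Violation(experiment.plate_id, label, "duplicate seed_index"))
        for seed in well.seeds:
            if seed.germinated:
                if seed.event_hour > experiment.censor_hour:
                    out.append(
                        Violation(experiment.plate_id, label, "event_hour beyond censor_hour")
                    )
                if not _on_time_grid(seed.event_hour, dt):
                    out.append(
                        Violation(
                            experiment.plate_id,
                            label,
                            f"event_hour {seed.event_hour} not on the {dt} h sampling grid",
                        )
                    )
    return out
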