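import pytest

from germkin.plate import (
    PlateExperiment,
    SeedRecord,
    WellObservation,
    WellPosition,
)


def make_well(
    event_hours,
    n_seeds=None,
    label="A1",
    genotype="Col-0",
    compound="water",
    dose_um=0.0,
):
    """Build a well with the given germination hours; extra seeds are censored."""
    events = list(event_hours)
    if n_seeds is None:
        n_seeds = len(events)
    assert n_seeds >= len(events)
    seeds = [
        SeedRecord(seed_index=i + 1, germinated=True, event_hour=float(h))
        for i, h in enumerate(events)
    ]
    seeds += [
        SeedRecord(seed_index=len(events) + j + 1, germinated=False)
        for j in range(n_seeds - len(events))
    ]
    return WellObservation(
        position=WellPosition.from_label(label),
        genotype=genotype,
        compound=compound,
        dose_um=dose_um,
        seeds=seeds,
    )


def make_experiment(wells, plate_id="P1", censor_hour=120.0, dt=1.0):
    return PlateExperiment(
        plate_id=plate_id,
        wells=wells,
        sampling_interval=dt,
        censor_hour=censor_hour,
    )


@pytest.fixture
def well_factory():
    return make_well


@pytest.fixture
def experiment_factory():
    return make_experiment
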