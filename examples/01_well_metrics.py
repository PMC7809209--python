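"""Kinetic metrics of a single well, from raw per-seed event hours.

Builds one 12-seed well in which 10 seeds germinate at known hours, then
extracts Gmax, the relative time quantiles t20/t50/t80 and the uniformity
U80-20 = t80 - t20.
"""

from germkin import SeedRecord, WellObservation, WellPosition, well_metrics

hours = [29, 30, 30, 31, 32, 33, 33, 35, 36, 40]  # 10 germinated seeds
seeds = [
    SeedRecord(seed_index=i + 1, germinated=True, event_hour=float(h))
    for i, h in enumerate(hours)
]
seeds += [SeedRecord(seed_index=11, germinated=False), SeedRecord(seed_index=12, germinated=False)]

well = WellObservation(
    position=WellPosition.from_label("C5"),
    genotype="Col-0", compound="water", dose_um=0.0, seeds=seeds,
)

m = well_metrics(well)  # default: relative metrics, >=3 germinated seeds required
print(f"Gmax    = {m.g_max:.2%}   ({m.n_germinated}/{m.n_seeds} seeds germinated)")
print(f"t20     = {m.t20:g} h     (hour of the ceil(0.2*10) = 2nd event)")
print(f"t50     = {m.t50:g} h")
print(f"t80     = {m.t80:g} h")
print(f"U80-20  = {m.u_80_20:g} h  (t80 - t20; smaller = more synchronous)")

# Gmax ~ 83% of sown seeds; the quantiles are hours since imbibition start.
# With fewer than 3 germinated seeds the time metrics would be None and the
# well flagged ineligible for summary tables.
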