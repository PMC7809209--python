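"""Plate-layout bias QC: the nine-test edge-effect battery and seed-density
regressions, run on four simulated null plates (no planted effect).

Each geometric grouping (ring = distance to the nearest border, row,
column) is tested against each index: Kruskal-Wallis on per-well t50 and
U80-20, chi-square homogeneity on pooled germinated/total counts for Gmax.
Under the null all nine p-values should look uniform; then the same data are
regressed on the per-well seed count s.
"""

from germkin import SimConfig, edge_effect_tests, null_experiment, regression_frame, seed_count_regressions

experiments, _ = null_experiment(SimConfig(rng_seed=11, n_plates=4))

report = edge_effect_tests(experiments)
print("edge-effect battery (null simulation, 4 plates):")
print(report[["metric", "grouping", "test", "p_value", "n_wells", "n_seeds"]].to_string(index=False))
# No p-value should be systematically small: well position does not bias
# germination in this design.

reg = regression_frame(seed_count_regressions(experiments, level=0.90))
print("\nindex ~ alpha + beta * seed_count (90% CIs):")
print(
    reg[["metric", "alpha_hat", "beta_hat", "se_beta", "ci_beta_low", "ci_beta_high", "r_squared"]]
    .round(4)
    .to_string(index=False)
)
# With no planted density effect every slope CI should cover 0; a real
# crowding effect would show up as positive slopes growing from t20 to t80.
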