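# Methods

## Data model

An experiment is one microplate (default 8×12) imaged at a fixed interval
Δt (default 1 h) up to a censor time T (default 120 h). Each well holds one
treatment (genotype, compound, dose in μM) and a list of seeds; a seed
either has a germination hour — the first frame at which radicle protrusion
is visible, stored as an absolute hour on the Δt grid — or is censored.
Censoring is experiment-level: whole plates are imaged together, so no
per-well censor override exists. Wells with zero seeds are treated as
invalid (flagged by `validate`, never silently dropped): a well without
seeds is a pipetting failure, not an observation.

The interchange format is a tidy long CSV (one row per seed; empty
`germination_hour` = censored; comma-separated, UTF-8, header required) and
a YAML plate map (explicit well lists or rectangular ranges such as
`A1:H6`; overlapping declarations are an error). Reading validates against
every model invariant and reports the offending line.

## Kinetic metrics

`Gmax = G/s` (G germinated of s sown) is always defined. Time quantiles use
a step rule: `t_x` is the hour of the ⌈x/100 · D⌉-th germination event,
with denominator D = G (relative metrics, default) or D = s (absolute).
Threshold arithmetic is exact (rational), so ⌈·⌉ never suffers float fuzz.
The step rule follows from hourly observation — interpolating between
frames would claim resolution the instrument does not have — and it
reproduces the degenerate t20 = t50 = t80 pattern of a well with a single
germinated seed. `U80-20 = t80 − t20`; it is 0 (not NA) when all quantiles
coincide.

Wells with G < `min_germinated` (default 3) are ineligible: time metrics
undefined, Gmax retained. The filter is applied uniformly in every
condition, not only stressed ones, so summaries are comparable across
doses.

Condition summaries report per-well means with population-style (ddof = 0)
standard deviations, computed over eligible wells for time metrics and over
all wells for Gmax; a seed-weighted pooled Gmax (Σ germinated / Σ sown) is
reported alongside the plain well mean, since both estimators are
defensible and they differ when seed counts vary. Because t20, t80 and
U80-20 are averaged over the same eligible-well set, the identity
mean(U80-20) = mean(t80) − mean(t20) holds exactly in every summary row.

Curve-level estimates pool seeds: the estimate at hour t is the
seed-count-weighted proportion, with a two-sided Clopper–Pearson band.
Weighting by seed count is the right estimator when the per-well count is
itself random; uniform well averaging would inflate the variance.

## Statistical conventions

- **Exact binomial CI**: Beta-quantile Clopper–Pearson with α/2 per tail;
  lower bound exactly 0 at k = 0, upper exactly 1 at k = n. Default level
  90% everywhere, matching the convention of the summary figures this
  layout mirrors.
- **Fisher 2×2**: two-sided, summing hypergeometric probabilities ≤ the
  observed table's.
- **Kruskal–Wallis**: tie correction is mandatory (hourly sampling produces
  heavy ties); p from χ² with k−1 df. An exact-permutation option
  enumerates all partitions for ≤ ~10 observations and serves as the
  small-sample oracle.
- **χ² homogeneity** for Gmax group tests operates on pooled
  germinated/not-germinated counts per group (k−1 df, no continuity
  correction). A rank test on per-well proportions is available as a
  switch; the count-based test is the default for proportions. Degenerate
  inputs (all values tied; all or no seeds germinated) return statistic 0,
  p = 1 rather than erroring: the null of homogeneity is trivially
  satisfied.
- **OLS**: closed-form fit with t-inference on n−2 df; two-sided p-values
  against zero coefficients; symmetric CIs at the stated level.
- No multiple-testing correction is applied anywhere: the nine-test battery
  reports nine uncorrected p-values, and readers should interpret them
  jointly.

## Layout diagnostics

`edge_effect_tests` crosses {t50, U80-20, Gmax} × {ring, row, column},
where ring = min distance of a well to the plate border (0-based; an 8×12
plate has rings 0–3; rings are invariant under 180° plate rotation and each
scheme partitions the 96 wells). Wells from all plates are pooled into one
population by default (a stratified per-plate run is just a loop over
experiments). Ineligible wells are excluded from the time-metric tests and
regressions but retained for Gmax; the report carries the exact well and
seed totals used per row, and a grouping with fewer than two nonempty
groups is flagged untestable instead of raising.

`conditional_means_by_count` mirrors the battery's estimands conditionally
on the seed count: t-based Gaussian CIs (n−1 df) for time metrics,
undefined at a single well; exact binomial CIs on pooled seeds for Gmax.

## Synthetic data generator

No public per-seed dataset of this kind exists, so the simulator defines
the study conditions and is itself first-class, tested code:

| parameter | default | meaning |
|---|---|---|
| seed count | round 𝒩(13, 4²), resampled into [5, 24] | pipetted-droplet variability |
| viability v₀ | 0.97 | eventual-germination probability in water |
| time law | log-normal, median m₀ = 33 h, log-sd σ = 0.10 | water-condition kinetics |
| dose response | v(d) = v₀ / (1 + (d/1.6)^1.5); median × (1 + 1.5·d/(d+3)) | Hill suppression + saturating delay (d in μM) |
| density effect β | 0 (off) | additive median delay, hours per seed vs the mean count |
| spatial effect | none | additive delay or viability shift for one geometric group |
| censor, Δt | 120 h, 1 h | imaging window and cadence |

Event times are snapped **up** to the next grid hour (germination is first
seen at the next image) and censored at T. σ = 0.10 is chosen so the
water-condition U80-20 lands on the observed few-hour scale; the dose
parameters are calibrated so doses {0, 1, 3, 10} μM produce the
characteristic Gmax cascade (≈0.97 → 0.6 → 0.3 → 0.04) — defaults, not
ground truth. The density effect is additive on the median (a log-shift
variant was considered and rejected: its convexity in s biases the fitted
linear slope upward by ≈3%, which would misrepresent the planted effect in
recovery studies). All randomness flows through one seeded numpy
`Generator`; identical (config, seed) gives byte-identical CSV.

What the simulator does **not** emulate: between-plate batch effects,
temperature or humidity drift over the imaging window, image-recognition
errors (miscounted seeds, mis-timed events), non-log-normal dormancy tails,
and seed-to-seed correlation within a well beyond the shared median.
Passing recovery and type-I tests on simulated data therefore validates the
statistical machinery under the stated generative model, not the instrument
or biology.

## Problem sizes and tolerances

Replicate studies in the test suite use 200 four-plate experiments for the
type-I study of the nine-test battery (rejection fraction at α = 0.05
checked against the Binomial(200, 0.05) 99.9% range, [0.01, 0.11], plus a
1%-level KS uniformity check) and 100 replicates of 374-well experiments
for density-slope recovery (90% CI coverage of β = 0.68 expected in
[80, 98] of 100). Interval coverage is checked with 10,000 binomial
replicates at n = 20. The acceptance script runs one plate for the
dose-response block and four plates each for the null battery and the
density-recovery block, analysing the first 374 wells in canonical order.

## Known limitations

- Quantiles are not interpolated; with coarse Δt the metrics inherit the
  grid's resolution.
- The exact-permutation Kruskal–Wallis is exponential in N and intended
  only as a ≤10-observation oracle.
- Absolute time metrics can be undefined even in healthy wells (the sown
  denominator may never be reached); downstream summaries must tolerate NA.
- The battery's p-values are marginal; no joint spatial model is fitted.
  The package tests for layout effects, it does not correct for them.
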