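# respiro

Analysis pipeline for soil-respirometry biodegradation experiments:

- **respirometry** — alkaline-trap back-titration records → per-day and
  cumulative net CO2 per microcosm, with control-baseline subtraction
  (net values floored at 0, raw differences retained for audit).
- **kinetics** — CH2-stoichiometry conversion of cumulative CO2 into a
  remaining-substrate trajectory (44 mg CO2 ↔ 14 mg hydrocarbon), and
  piecewise first-order rate-constant estimation (1–3 contiguous phases,
  continuity of C at breakpoints, exhaustive breakpoint search over
  observed sampling days, ln-space RMSE objective with a linear-space
  switch).
- **mass_balance** — endpoint carbon partition: mineralized (12/44),
  residual diesel-range organics with surrogate-recovery correction,
  biomass from nitrogen depletion (C5H7O2N: 60 mg C per 14 mg N),
  an assumed volatilization allowance (0–20%), and a closing
  unaccounted term so components always sum to 100%.
- **stats_compare** — paired two-tailed t-test, one-way ANOVA with
  Tukey HSD post hoc (applied only when the omnibus test is significant
  at α = 0.05), standard errors; zero-variance inputs return flagged
  results instead of NaN.
- **synthetic_data** — a reproducible microcosm generator (titration
  records, nitrogen budgets, endpoint DRO, booked true fractions) so
  every pipeline stage is testable without external data, including the
  suspended-grid/volatiles mode with a post-water-addition respiration
  step.
- **cli_io / pipeline** — CSV readers/writers, YAML configuration, and
  end-to-end orchestration.

## CLI

```sh
# generate a synthetic cohort (metadata.csv, titration.csv, endpoint.csv, truth.json)
respiro simulate --out sim/ --seed 1 --replicates 3

# full analysis: respirometry -> kinetics -> mass balance -> stats
respiro analyze --metadata sim/metadata.csv --titration sim/titration.csv \
    --endpoint sim/endpoint.csv --out report/

# kinetics-only fit report
respiro fit --metadata sim/metadata.csv --titration sim/titration.csv

# pretty-print a summary
respiro report --summary report/summary.json

# suspended-grid (volatiles) experiment, 41 days with water addition at day 28
respiro simulate --out grid/ --seed 1 --grid --days 41
```

`analyze` writes `respiration.csv`, `fits.csv`, `k_summary.csv`,
`balance.csv`, `stats.csv` and `summary.json`; runs are deterministic —
identical inputs give identical bytes.

## Input formats

- metadata CSV: `microcosm_id, fuel, fuel_mass_mg, soil_mass_g,
  n_added_mg, setup, replicate, temperature_c`
  (fuel ∈ DIESEL, HTG, SYNTROLEUM, B20, B100, CONTROL; setup ∈
  SOIL_BED, GRID_WITH_SOIL, GRID_NO_SOIL)
- titration CSV: `microcosm_id, day, blank_volume_ml, sample_volume_ml,
  normality` (or pre-converted `microcosm_id, day, co2_mg` via `--co2`)
- endpoint CSV: `microcosm_id, dro_measured_mg, surrogate_recovery,
  n_final_mg`

Each cohort needs at least one CONTROL microcosm per setup for baseline
subtraction.

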