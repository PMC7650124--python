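# lcm — life-course socioeconomic mobility analysis

`lcm` analyses matched case-control data on socioeconomic position across
the life course. It implements:

- **Scoring** — additive disadvantage point scores for childhood (0–12,
  nine questionnaire items), adolescence (0–8, school degree +
  professional education) and adulthood (0–8, last profession +
  unemployment + partnership), with deterministic mode-per-cell
  imputation of missing items.
- **Mobility classification** — intergenerational occupational mobility
  (father vs. professional training vs. last profession over the ordered
  categories academic > white-collar > blue-collar/other) and
  score-stratum mobility between life stages, where strata are cut at
  the tertiles of the *control* score distribution.
- **Conditional logistic regression** — exact conditional likelihood
  over 2-year-age-band × sex strata, with the subset-sum denominator
  computed by recursion (numba-accelerated), Newton–Raphson fitting,
  Wald odds-ratio intervals, and explicit flagging of uninformative
  strata, dropped covariates and separation.
- **Pipeline** — three nested model variants per mobility exposure
  (conditioning only; + 14 medical/lifestyle risk factors; + life-stage
  score strata), mobility count/percentage tables, crude 2×2
  diagnostics, and sex-stratified fully adjusted fits.
- **Synthetic data** — a Gaussian-copula-style generator for
  frequency-matched studies with configurable latent life-course
  correlations and true odds ratios, used for end-to-end parameter
  recovery and calibration testing.

## CLI

```sh
# generate a synthetic matched study (writes study.csv + study.csv.truth.json)
lcm simulate --config sim.yaml --out study.csv --seed 1

# full analysis: table1.csv, table2.csv, fits.json, bysex.csv, cutpoints.json,
# run.log and config_resolved.yaml in the output directory
lcm analyze --input study.csv --out results/ --seed 1

# counts/percentage tables only, or schema validation
lcm tables --input study.csv --out results/
lcm validate --input study.csv
```

Configs are flat YAML files whose keys mirror `SimulationConfig`
(simulate) and `AnalysisConfig` (analyze/tables); unknown keys are
rejected. All randomness flows from the single `seed`, and identical
seed + config reproduce byte-identical outputs.

The study CSV schema is one row per subject:
`id, status{case,control}, age_years, sex{m,f}`, the 14 socioeconomic
items, and 14 binary risk-factor columns; empty string = missing (see
`lcm/records.py` for the exact column list and levels).

## Library use

```python
from lcm import SimulationConfig, simulate_study, AnalysisConfig, run_analysis

study, truth = simulate_study(SimulationConfig(seed=1))
result = run_analysis(study, AnalysisConfig(seed=1))
print(result.table_scores)            # counts, percentages, OR (95% CI)
fit = result.fit("adol_adult", "model3")
print(fit.or_ci["adol_adult_descent"])
```
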