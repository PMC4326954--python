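# agemarkers

Classify longitudinal phenotype features of inbred mouse strains into
**pro-longevity**, **antilongevity** and **role-switching** biomarkers of
aging by combining four kinds of evidence:

1. **Longitudinal trends** — per sex, each feature is standardized and
   regressed on age (OLS); the slope's two-sided t-test decides the trend
   call, and the slope converts exactly to the feature–age Pearson
   correlation (`r = slope × SD(age)`).
2. **Prognostic evidence** — per sex × age group, the Pearson correlation
   between feature value and strain life expectancy; a cell is *relevant*
   when `|r| ≥ 0.2` and `p < 0.05`. Isolated relevant cells at the
   volatile old age groups (18/20/24 months) are masked.
3. **Effect annotations** — a curated table of literature effect valences
   that validates trends (beneficial effect + downtrend, or deleterious
   effect + uptrend, marks a biomarker of *aging* rather than of age).
4. **Proportional-hazards cross-checks** — univariate/multivariate Cox
   fits of life expectancy on standardized features (Efron ties by
   default), displayed with the inverted sign so "good for lifespan"
   points the same way as a positive lifespan correlation.

Corroborating prognostic and validated-longitudinal evidence gives a
clear-cut class; conflicting evidence resolves to a **role switch**
(early class from the prognostic side, late class from the validated
longitudinal side), as does a prognostic sign switch across age groups.
A synthetic cohort generator with a planted-truth table makes every stage
testable without any external download, and a strain-stratification stage
re-runs the analysis without short-lived strains and compares per-strain
trend speeds against the longer-lived reference.

## CLI

All subcommands share one YAML config (see `examples/pipeline.yaml`):

```bash
agemarkers run       --config examples/pipeline.yaml --out out/ --seed 7 --no-plots
agemarkers simulate  --config examples/pipeline.yaml --out out/        # cohort + truth table
agemarkers trends    --config examples/pipeline.yaml --out out/
agemarkers prognostic --config examples/pipeline.yaml --out out/
agemarkers cox       --config examples/pipeline.yaml --out out/
agemarkers classify  --config examples/pipeline.yaml --out out/
agemarkers compare   --config examples/pipeline.yaml --out out/
```

`run` writes `trends.csv`, `prognostic.csv`, `cox.csv`,
`classification.csv`, `classification_longlived.csv` (re-analysis without
the short-lived strains), `comparison.csv` (per-strain trend-speed
categories), `chartspec.json` (bar panels in regression order with open
bars for irrelevant cells and the two red delimiters) and a deterministic
`manifest.json` (seed, thresholds, version, per-stage row counts).

Instead of a `synthesize:` block, the config may point at CSV inputs:

```yaml
inputs:
  phenotypes: phenotypes.csv    # animal_id, strain, sex, age_months, <features...>
  lifespans: lifespans.csv      # strain, sex, life_expectancy[, event_observed]
  annotations: annotations.csv  # feature_name, early_effect, late_effect, label, source
```

## Package layout

| Module | Purpose |
| --- | --- |
| `agemarkers.data_model` | domain types, CSV I/O, lifespan merge, percentage→count derivation |
| `agemarkers.synthetic` | cohort generator + planted-truth table |
| `agemarkers.trends` | standardization, OLS trend fits, slope→r conversion, slope ordering |
| `agemarkers.prognostic` | lifespan correlations with relevance rule, Cox fits |
| `agemarkers.classify` | volatile-age filter, trend validation, rule-based classification, qualifiers |
| `agemarkers.stratify` | strain exclusion, short- vs longer-lived trend comparison |
| `agemarkers.charts` | chart-spec construction and optional rendering |
| `agemarkers.pipeline` / `agemarkers.cli` | end-to-end orchestration and command line |
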