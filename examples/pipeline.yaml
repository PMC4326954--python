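# End-to-end pipeline configuration with a synthetic cohort.
# Replace the `synthesize:` block with an `inputs:` block (phenotypes,
# lifespans, annotations CSV paths) to analyse real data.
seed: 7
cox: true

synthesize:
  n_strains: 30
  n_animals_per_strain_sex: 8
  age_groups: [6, 12, 18, 24]
  lifespan_mean: 26
  lifespan_sd: 5
  short_lived: {n_strains: 6, lifespan_cap: 18, dropout: false}
  features:
    - name: f_pro            # declines with age, prognostic for long lifespan
      trend_slope: -0.04
      prognostic_r: {6: 0.5, 12: 0.5, 18: 0.4, 24: 0.4}
      early_effect: beneficial
      late_effect: beneficial
    - name: f_anti           # rises with age, prognostic for short lifespan
      trend_slope: 0.04
      prognostic_r: {6: -0.5, 12: -0.5}
      early_effect: deleterious
      late_effect: deleterious
    - name: f_switch         # prognostic sign switch across age groups
      trend_slope: -0.04
      prognostic_r: {6: -0.5, 12: 0.5, 18: 0.5}
      early_effect: deleterious
      late_effect: beneficial
    - name: f_conflict       # prognosis short early, validated downtrend late
      trend_slope: -0.04
      prognostic_r: {6: -0.5, 12: -0.4}
      early_effect: deleterious
      late_effect: beneficial
    - name: f_age            # trend without prognosis or known effect
      trend_slope: 0.05
    - name: f_null           # pure noise
      trend_slope: 0.0

thresholds:
  alpha: 0.05
  r_min: 0.2
  qualifier_margin: 0.15
  volatile_ages: [18, 20, 24]
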