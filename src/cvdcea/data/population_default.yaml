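# Default synthetic-population configuration emulating the schema and marginal
# structure of a national fasting-subsample survey of US adults aged 19-64
# (n = 8,141). Subgroup fractions follow the study population; risk-factor
# marginals and correlations are synthetic, field-plausible defaults.
n: 8141
age_min: 19
age_max: 64
female_fraction: 0.51
pop_scale: 189980531.0
weight_sigma: 0.3            # lognormal sd of survey weights (mean weight = pop_scale/n)

fractions:
  medicaid_eligible: 0.10
  cvd_history: 0.05
  income:                    # sums are normalised within each partition
    poor: 0.18
    near_poor: 0.06
    low: 0.15
    medium: 0.28
    high: 0.34
  education:
    no_degree: 0.14
    ged_hs: 0.22
    associate_bachelor: 0.33
    master_doctorate: 0.31
  race_ethnicity:
    Asian: 0.06
    Black: 0.12
    Hispanic: 0.17
    Other: 0.04
    White: 0.61

uninsured_above_fpl: 0.12    # P(uninsured) for income bands above the 138% FPL cutoff
smoker_fraction: 0.18
htn_treatment_fraction: 0.17

risk_factors:
  sbp: {dist: normal, mean: 122.0, sd: 15.0}
  total_chol: {dist: normal, mean: 190.0, sd: 35.0}
  hdl_chol: {dist: normal, mean: 52.0, sd: 14.0}
  hba1c: {dist: shifted_lognormal, shift: 4.5, mu: 0.095, sigma: 0.5}
  bmi: {dist: normal, mean: 29.0, sd: 6.5}

# Gaussian-copula correlations, order (sbp, total_chol, hdl_chol, hba1c, bmi)
copula_correlation:
  - [1.00, 0.15, -0.05, 0.15, 0.25]
  - [0.15, 1.00, -0.20, 0.10, 0.10]
  - [-0.05, -0.20, 1.00, -0.15, -0.25]
  - [0.15, 0.10, -0.15, 1.00, 0.30]
  - [0.25, 0.10, -0.25, 0.30, 1.00]
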