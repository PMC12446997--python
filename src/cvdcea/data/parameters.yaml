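# Default model parameters (2021 USD). Coefficient tables live in the CSV files
# alongside this file; everything here is overridable through RunConfig /
# ParameterSet.with_scalar. Values without a printed literature source are
# synthetic defaults chosen for realism and are marked as such in the docs.
wtp: 150000.0                # willingness to pay, USD per QALY
epsilon: 0.5                 # Atkinson inequality aversion, base case
discount_rate: 0.03
max_age: 85                  # model horizon: simulate until death or this age
medicare_age: 65             # Medicaid cost effects cease at this age
retirement_age: 65           # lost-earnings accrual stops at this age
population_n: 189980531      # weighted US adult population (ages 19-64) the sample represents

intervention:
  delta_sbp: -3.03           # mm Hg, one-time reduction for Medicaid recipients
  delta_sbp_ci: [-5.33, -0.73]
  delta_hba1c: -0.14         # percentage points
  delta_hba1c_ci: [-0.24, -0.03]

econ:
  event_markup: 1.33                 # health-care cost multiplier in an MI/stroke year
  expansion_cost_multiplier: 2.13    # recipients' total annual health-care cost multiplier
  preventive_cost: 240.0             # USD/yr, routine visits + prescriptions for recipients
  admin_cost_per_enrollee: 550.0     # USD/yr government administration per enrollee
  admin_cvd_share: 0.066             # share of Medicaid admin spending apportioned to CVD
  avg_annual_earnings: 58120.0       # USD, average annual earnings (lost on premature death)
  productivity_event_cost: 7500.0    # USD, absenteeism + short-term disability in event year
  oop_share_uninsured: 0.40          # fraction of health-care cost paid out of pocket
  oop_share_medicaid: 0.03
  oop_share_insured: 0.14

diabetes_hba1c_threshold: 6.5   # percent; diabetes status derived from HbA1c

# Age/sex-matched reference used to centre the risk equations and as the
# denominator profile for the relative-risk weighting (race fixed at White,
# stratum-mean risk factors).
reference_profile:
  age: 50
  sbp: 122.0
  total_chol: 190.0
  hdl_chol: 52.0
  smoker: false
  diabetes: false
  on_htn_treatment: false

bounds:
  sbp: [80.0, 250.0]
  total_chol: [80.0, 500.0]
  hdl_chol: [10.0, 150.0]
  hba1c: [3.0, 15.0]
  bmi: [12.0, 80.0]
  age: [19, 64]

# Family-income bands relative to the federal poverty line: bands below the
# 138% FPL Medicaid-expansion cutoff, and bands above the 150% FPL line that
# bear the cost redistribution. "low" straddles and is assigned above 150% FPL
# by default.
income_below_138: [poor, near_poor]
income_above_150: [low, medium, high]
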