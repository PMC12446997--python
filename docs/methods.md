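# Methods

## Model structure

A closed-cohort, annual-cycle Monte Carlo Markov-chain microsimulation
compares two arms over the same cohort of US adults aged 19–64: *expansion*
(Medicaid-eligible individuals — uninsured, income below 138% FPL — receive
the intervention) and *nonexpansion*. Individuals begin in `no_cvd` or
`history_cvd`. Each cycle, conditional on first surviving non-CVD death, a
single categorical draw selects nonfatal/fatal MI, nonfatal/fatal stroke, or
no event; survivors of an event carry `history_cvd` (doubled event risk) from
the next cycle. Death states are absorbing; recurrent events are allowed. The
horizon runs to death or age 85 (`lifetime`), with `10yr` and `to65` options.
Everyone switches to Medicare at 65: expansion stops generating *cost*
differences from that age, while risk-factor effects persist.

The intervention is a one-time reduction at entry in systolic blood pressure
(−3.03 mm Hg; 95% CI −5.33 to −0.73) and HbA1c (−0.14 pp; 95% CI −0.24 to
−0.03) for eligible individuals in the expansion arm, floored at physiologic
bounds; the diabetes flag is re-derived from HbA1c against a 6.5% threshold,
so the HbA1c reduction can flip diabetes status.

## Transition probabilities

Annual MI and stroke rates come from sex-specific proportional-hazards
equations differentiating event type:
`rate = −ln(S0_1yr) · exp(LP − LP_ref)`, with log-age, log-SBP
(treated/untreated), log-cholesterol, smoking and diabetes terms, centred at a
configurable reference profile (age 50, SBP 122, TC 190, HDL 52, nonsmoking,
nondiabetic, untreated). Rates are then multiplied by the ratio of the
individual's 10-year pooled-cohort-style (ASCVD) risk to that of an
age-sex-matched reference with stratum-mean risk factors and race White. This
multiplicative relative-risk weighting imports the finer race/SBP/diabetes
gradients while preserving the event-type split; it is the identity for an
individual matching the reference profile. The ×2 history multiplier is
applied after the weighting (the two commute under the multiplicative form;
the order is pinned). Rates convert to probabilities via `1 − exp(−rate)`;
the combined MI+stroke probability is capped at 0.99 with proportional
rescaling and a logged count when binding (it binds only in extreme
risk-factor tails).

Fatal-to-total fractions are age–sex logistics. Non-CVD death is the
all-cause rate minus MI and stroke death rates from an age–sex table
(ages 19–85), converted to a probability.

**Coefficient provenance.** The published study cites literature sources for
the risk equations, fatal fractions, mortality rates and cost/utility
regression but does not print the coefficient values. The packaged tables
(`src/cvdcea/data/*.csv`) are therefore *synthetic fixtures* with
field-plausible magnitudes and the correct structural form, fully overridable
through the config files. All tests bind to the fixtures, not to literature
values; absolute levels (incidence, costs) are fixture-dependent, structural
behaviour (directions, invariances, equity ordering) is not.

## Costs, utilities, redistribution

Annual health-care cost (2021 USD) and utility (SF-6D in [0,1], clipped) are
linear predictions over age, sex, race/ethnicity, income, education, CVD
history, current-cycle event, diabetes, BMI and smoking. Event years multiply
health-care cost by 1.33 and add a utility decrement. One cycle's utility is
that cycle's QALY contribution before half-cycle weighting. Productivity
costs: an event-year absenteeism/disability cost, plus 100% of average annual
earnings for every year from a premature death (death age inclusive) to
retirement at 65, discounted from the death cycle. The counting is inclusive
of the death year — a death at 63 with $60,000 earnings loses $120,000
undiscounted (ages 63 and 64) — chosen to match the convention that the
death-year's production is lost even though person-time accrues half a cycle.

Expansion cost effects, for recipients under 65: total health-care cost is
multiplied by 2.13 (the recipients' utilisation increase; config), a
preventive-care cost ($240/yr) is added, administration is
$550/enrollee/yr × 6.6% CVD share, and out-of-pocket (OOP) share drops from
the uninsured share (0.40) to the Medicaid share (0.03). Two cost views are
maintained:

* **resource view** — health care + administration + productivity; invariant
  to who pays. Conservation: the expansion arm's weighted resource total
  equals the nonexpansion total plus the true resource increase, independent
  of the OOP/non-OOP split (asserted to 1e-9 relative).
* **attributed (incidence) view** — used for the distributional tables:
  each person bears their baseline-utilisation health-care cost and
  productivity loss; recipients get their OOP relief; the weighted total of
  the utilisation increase plus administration is levied evenly per weighted
  person on individuals above 150% FPL. The levy is computed on discounted
  per-person totals after both arms have run, which keeps it consistent with
  the discounting of the costs it redistributes.

The five income bands map to the two FPL cutoffs by config: `poor` and
`near_poor` lie below 138% FPL (eligibility); `medium` and `high` above 150%
FPL (levy); `low` straddles and is assigned above 150% by default. The
perspective is limited-societal (health care + productivity, no consumption
or caregiver costs); a healthcare-only perspective is available.

Half-cycle correction: QALYs, annual costs and person-years accrue half
weight in the entry cycle and the death cycle (one-time quantities — event
productivity cost, lost-earnings stream — are discounted but not
half-weighted). Discounting is 3%/yr.

## DCEA

Cost-effectiveness: NHB = E − C/λ per person; INHB is the between-arm
difference, base case λ = $150,000/QALY. Equity operates on *per-subgroup
mean net health* weighted by population fraction — matching the reported
group-level structure, not person-level NHB — for three partitions: family
income, education, race/ethnicity. The Atkinson EDE
(`(Σ wᵢhᵢ^(1−ε))^(1/(1−ε))`, log form at ε = 1) yields EDEH per arm, IEDEH,
the Atkinson index `Aε = 1 − EDEH/NHB`, and the population inequality-burden
change `[(Aε·NHB)_nonexp − (Aε·NHB)_exp] × N` with N = 189,980,531. Base-case
ε = 0.5, grid {0, 0.5, …, 3}. The Atkinson decomposition requires positive
group net health; non-positive means are reported as undefined (NaN with a
diagnostic) rather than silently shifted, since any affine shift changes the
index. Lifetime-scale NHB is positive throughout the packaged configurations.
The break-even aversion solves IEDEH(ε) = 0 by Brent bisection on [0, 20]
(tolerance 1e-4), reporting none when there is no sign change.

Equity-efficiency plane: y = population INHB, x = population (IEDEH − INHB);
bottom-right = not cost-effective but equity enhancing.

## Randomness and replication

All randomness flows from named integer seed keys through
`numpy.random.SeedSequence`. One uniform tensor (person × cycle × 3 draws:
non-CVD death, event, fatality) is drawn per replication key and shared by
both arms — the arm never enters any seed key. This is the common-random-
numbers guarantee: with zero intervention effects and zero cost deltas, every
incremental quantity is exactly zero (asserted end to end). Row *i* of the
tensor is individual *i*'s stream, so per-individual trajectories are
reproducible in isolation.

PSA draws one parameter vector per replication: normal for the intervention
effects (SD from the 95% CIs, (upper−lower)/(2×1.959964)), gamma for cost
parameters (CV 0.2; the utilisation multiplier is gamma on its excess over
1), beta for the utility intercept (SD 0.02) — declared defaults, not hidden
choices. Bootstrap resampling is with replacement per replication; Rubin's
rules pool across imputation replicates (the generator emits complete data;
replicates jitter continuous risk factors by 2% of each marginal SD to
exercise the pooling, since imputation modelling itself is out of scope).
The one-way DSA sweeps cost-side parameters and the discount rate by ±20%,
excluding (with a logged reason) anything feeding transition probabilities.

## Synthetic population

The generator reproduces the target weighted fractions (Medicaid-eligible
0.10, CVD history 0.05, and the income/education/race strata) within ±0.02
at n ≥ 5,000. Printed survey tables round to two decimals, so partitions may
sum slightly off 1 (the income bands sum to 1.01); targets are normalised
within each partition. Eligibility is derived — uninsured ∧ income below
138% FPL ∧ age 19–64 — with the uninsured probability below the cutoff set so
the eligible fraction hits its target; above the cutoff it is 0.12. Risk
factors co-move through a Gaussian copula (SBP, total and HDL cholesterol,
HbA1c, BMI) with configurable correlations and normal / shifted-lognormal
marginals clipped to physiologic bounds; diabetes is derived from HbA1c ≥
6.5%. Survey weights are lognormal (σ = 0.3) scaled to a weighted population
of 189,980,531.

What the generator does *not* emulate: real joint distributions beyond the
copula (e.g. income×education dependence), survey design (strata/PSU),
item missingness, or state-level heterogeneity. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's mechanics on a
population with the right schema and marginals — not agreement with estimates
that depend on the real survey microdata or on the unpublished literature
coefficient values.

## Problem sizes

Defaults chosen for desk-scale runs: cohort n = 8,141 in the drivers;
tests use n = 500–5,000; direction-of-effect recovery uses n = 5,000 with 20
replications; PSA drivers use 2 imputation replicates × 25 bootstrap
replications at n = 2,000. The engine is vectorised over the cohort (one
run of both arms at n = 8,141 takes a few seconds on one core), and full-scale
replication (10 × 2,000) is a parameter change, not a code path.

## Known limitations

* Fixture coefficient tables are synthetic; absolute incidence, cost and
  INHB levels should not be read as empirical estimates.
* The utilisation multiplier (2.13) applies to the full predicted health-care
  cost for the whole pre-65 horizon; if utilisation increases attenuate over
  time, lifetime expansion costs are overestimated.
* Only the first event per cycle is possible (single categorical draw);
  same-year MI+stroke combinations are excluded.
* Survivors past the age-85 horizon stop accruing rather than dying; the
  final cycle receives full (not half) weight unless it is a death cycle.
* The Medicaid cohort is closed: no churn in or out of eligibility, constant
  effects, no post-65 policy effects beyond persisted risk factors.
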