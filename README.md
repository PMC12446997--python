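# cvdcea

Distributional cost-effectiveness analysis (DCEA) of Medicaid expansion and
cardiovascular disease, implemented as a tested, reusable microsimulation
pipeline.

Expanding Medicaid to uninsured adults (aged 19–64, family income below 138%
of the federal poverty line) lowers recipients' systolic blood pressure and
HbA1c, which in turn lowers their risk of myocardial infarction (MI) and
stroke — but it also raises their health-care utilisation, and those extra
costs (plus programme administration) are ultimately borne by households above
150% FPL. Whether the policy is *worth it*, and *for whom*, is therefore both
an efficiency question and an equity question. This package answers both with:

1. **A synthetic population generator** emulating the schema and marginal
   structure of a national fasting-subsample survey (demographics, SES strata,
   insurance, CVD risk factors, survey weights), so every stage is testable
   without data downloads.
2. **A risk engine** producing annual per-person transition probabilities:
   sex-specific proportional-hazards MI/stroke equations re-weighted by a
   pooled-cohort-style relative risk, a ×2 multiplier for CVD history,
   age–sex fatal-event fractions, and non-CVD mortality from an age–sex table.
3. **A two-arm annual-cycle Monte Carlo Markov-chain microsimulation**
   (expansion vs nonexpansion) under common random numbers, lifetime horizon
   to age 85, half-cycle correction, Medicare switch at 65, 3% discounting.
4. **An economic layer**: predicted annual health-care costs (2021 USD) and
   SF-6D utilities, a 33% event-year cost markup, productivity losses, and the
   expansion cost redistribution (recipients' out-of-pocket costs fall; the
   increase in their total costs plus administration is levied evenly on
   incomes above 150% FPL).
5. **A DCEA layer**: (incremental) net health benefit, Atkinson
   equally-distributed-equivalent health (EDEH), Atkinson index, population
   inequality burden, and the equity-efficiency plane.
6. **Replication machinery**: bootstrap × imputation loops, Rubin's rules,
   Monte Carlo standard errors, PSA with acceptability curves, one-way ±20%
   tornado analysis, and DCEA-PSA quadrant probabilities.

## The core quantities

With willingness to pay λ (USD/QALY), per-person incremental costs ΔC and
effects ΔE:

```
INHB = ΔE − ΔC / λ                      (incremental net health benefit, QALYs)
EDEH_ε = (Σᵢ wᵢ hᵢ^(1−ε))^(1/(1−ε))     (Atkinson EDE of subgroup net health hᵢ)
A_ε = 1 − EDEH / NHB                    (Atkinson inequality index)
```

IEDEH (the incremental EDEH between arms) is the equity-adjusted INHB: when
IEDEH > INHB the intervention's redistribution is equity enhancing at
aversion ε. Base case: λ = $150,000/QALY, ε = 0.5, 3% discount.

## Worked example

```python
>>> from cvdcea.dcea import incremental_net_health_benefit
>>> incremental_net_health_benefit(-26.0, 0.0029, 150_000)   # ΔC, ΔE, λ
0.0030733333333333334
```

A per-person saving of $26 alongside a 0.0029-QALY gain is worth 0.0031 QALYs
(4 dp) per person at $150,000/QALY — cost saving *and* health improving, hence
INHB exceeds ΔE alone.

Full pipeline (the numbered drivers under `analysis/` wrap these steps and
write CSVs under `results/`):

```
python analysis/01_build_population.py 1   # synthetic cohort + calibration check
python analysis/02_base_case.py 1          # two-arm run, incidence, subgroup table
python analysis/03_sensitivity.py 1        # tornado, PSA/CEAC, DCEA-PSA quadrants
python analysis/04_equity_plane.py 1       # equity-efficiency plane, IEDEH over ε
```

With the packaged synthetic defaults (n = 8,141, seed 1) the base-case driver
prints

```
total: dC=+7,241 USD, dE=+0.0098 QALYs, INHB=-0.0385 QALYs at lambda=$150,000
income_group: IEDEH=-0.0376, quadrant=bottom-right, population burden change=+173,929 QALYs
```

read as: expansion improves health (+0.0098 QALYs/person) but, under the
synthetic cost fixture, the utilisation increase outweighs the benefit at
$150,000/QALY (INHB < 0), while the income partition lands in the
bottom-right plane quadrant — not cost-effective overall, yet equity
*enhancing* (IEDEH > INHB), because the gains accrue to low-income groups and
the levy falls on high-income groups. Absolute cost magnitudes depend on the
packaged fixture coefficient tables (see `docs/methods.md`); the incidence
reductions, redistribution direction and equity ordering are the structural
results.

## Layout

```
src/cvdcea/            library: synthetic_population, risk_engine, microsim,
                       econ, dcea, uncertainty, reporting, params
src/cvdcea/data/       fixture coefficient tables + default configs (editable)
analysis/              numbered narrative drivers writing results/*.csv
tests/                 pytest suite (unit, property, acceptance)
docs/methods.md        model documentation and design decisions
```
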