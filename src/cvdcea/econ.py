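"""Costs, utilities, discounting, and the expansion cost redistribution.

Annual health-care cost (2021 USD) and utility (SF-6D scale) come from a
linear prediction equation over demographics, socioeconomic strata, CVD
history, current-cycle event, diabetes, BMI and smoking, with coefficients
shipped as an overridable fixture table. Event years multiply health-care
cost by a 33% markup. Productivity costs cover event-year absenteeism and
full lost earnings from premature death until retirement. The expansion is
modelled as a wealth transfer: recipients' out-of-pocket (OOP) costs fall
while the increase in their total health-care cost plus programme
administration is levied evenly (per weighted person) on individuals with
family income above 150% of the federal poverty line.

Two cost views coexist:

* resource view — real resources consumed (health care + administration +
  productivity); invariant to who pays, used for conservation checks.
* attributed (incidence) view — what each person/subgroup bears after the
  OOP relief and redistribution levy; used for the distributional tables.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import CoefficientError
from .params import ParameterSet

_STATIC_TERMS = {
    "male": lambda df: (df["sex"] == "male").to_numpy(float),
    "race_Black": lambda df: (df["race_ethnicity"] == "Black").to_numpy(float),
    "race_Hispanic": lambda df: (df["race_ethnicity"] == "Hispanic").to_numpy(float),
    "race_Asian": lambda df: (df["race_ethnicity"] == "Asian").to_numpy(float),
    "race_Other": lambda df: (df["race_ethnicity"] == "Other").to_numpy(float),
    "income_poor": lambda df: (df["income_group"] == "poor").to_numpy(float),
    "income_near_poor": lambda df: (df["income_group"] == "near_poor").to_numpy(float),
    "income_low": lambda df: (df["income_group"] == "low").to_numpy(float),
    "income_medium": lambda df: (df["income_group"] == "medium").to_numpy(float),
    "edu_no_degree": lambda df: (df["education"] == "no_degree").to_numpy(float),
    "edu_ged_hs": lambda df: (df["education"] == "ged_hs").to_numpy(float),
    "edu_associate_bachelor": lambda df: (df["education"] == "associate_bachelor").to_numpy(float),
    "diabetes": lambda df: df["diabetes"].to_numpy(float),
    "smoker": lambda df: df["smoker"].to_numpy(float),
}

REQUIRED_TERMS = ("intercept", "age_minus45", "cvd_history", "event_cycle", "bmi_minus28") + tuple(
    _STATIC_TERMS
)


def _check_terms(coefs: dict[str, float], which: str) -> None:
    missing = [t for t in REQUIRED_TERMS if t not in coefs]
    if missing:
        raise CoefficientError(f"{which} model missing coefficient(s): {missing}")


def static_linear_predictors(df: pd.DataFrame, params: ParameterSet):
    """Per-person cost and utility contributions that never change over cycles.

    Includes the intercept and BMI term; excludes age, CVD history and the
    event flag, which the cycle loop adds.
    """
    _check_terms(params.cost_coefs, "cost")
    _check_terms(params.utility_coefs, "utility")
    n = len(df)
    cost = np.full(n, params.cost_coefs["intercept"])
    util = np.full(n, params.utility_coefs["intercept"])
    bmi_c = df["bmi"].to_numpy(float) - 28.0
    cost += params.cost_coefs["bmi_minus28"] * bmi_c
    util += params.utility_coefs["bmi_minus28"] * bmi_c
    for term, getter in _STATIC_TERMS.items():
        x = getter(df)
        cost += params.cost_coefs[term] * x
        util += params.utility_coefs[term] * x
    return cost, util


def annual_cost_utility(df: pd.DataFrame, params: ParameterSet, age=None,
                        cvd_history=None, event=None, static=None):
    """Annual health-care cost and utility for the current cycle.

    Event cycles multiply cost by the 33% markup and add the event utility
    decrement. Utility is clipped to [0, 1]; one cycle's utility is that
    cycle's QALY contribution (before half-cycle weighting).
    """
    if static is None:
        static = static_linear_predictors(df, params)
    cost_s, util_s = static
    age = df["age"].to_numpy(float) if age is None else np.asarray(age, dtype=float)
    hist = df["cvd_history"].to_numpy(float) if cvd_history is None else np.asarray(
        cvd_history, dtype=float
    )
    ev = np.zeros(len(df)) if event is None else np.asarray(event, dtype=float)
    age_c = age - 45.0
    cost = (
        cost_s
        + params.cost_coefs["age_minus45"] * age_c
        + params.cost_coefs["cvd_history"] * hist
        + params.cost_coefs["event_cycle"] * ev
    )
    cost = np.maximum(cost, 0.0)
    markup = params.econ["event_markup"]
    cost = cost * np.where(ev > 0, markup, 1.0)
    util = (
        util_s
        + params.utility_coefs["age_minus45"] * age_c
        + params.utility_coefs["cvd_history"] * hist
        + params.utility_coefs["event_cycle"] * ev
    )
    return cost, np.clip(util, 0.0, 1.0)


def oop_share(insured, medicaid: bool | np.ndarray, params: ParameterSet):
    """Fraction of health-care cost paid out of pocket, by coverage status."""
    e = params.econ
    insured = np.asarray(insured, dtype=bool)
    medicaid = np.asarray(medicaid, dtype=bool)
    out = np.where(insured, e["oop_share_insured"], e["oop_share_uninsured"])
    return np.where(medicaid, e["oop_share_medicaid"], out)


def discount_factor(cycle, rate: float):
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


def discount_accumulate(amounts, half_cycle_weights, rate: float) -> float:
    """Sum per-cycle amounts × half-cycle weights × (1+r)^(-cycle)."""
    amounts = np.asarray(amounts, dtype=float)
    w = np.asarray(half_cycle_weights, dtype=float)
    if amounts.shape != w.shape:
        raise ValueError("amounts and weights must align")
    cycles = np.arange(amounts.shape[-1])
    return float(np.sum(amounts * w * discount_factor(cycles, rate), axis=-1))


def lost_earnings_present_value(death_age, death_cycle, params: ParameterSet,
                                discount: bool = True):
    """PV (at entry) of full annual earnings lost from death until retirement.

    Years are counted from the death age inclusive up to (exclusive) the
    retirement age; the first lost year is discounted at the death cycle.
    """
    death_age = np.asarray(death_age, dtype=float)
    death_cycle = np.asarray(death_cycle, dtype=float)
    k = np.maximum(params.retirement_age - death_age, 0.0)
    earnings = params.econ["avg_annual_earnings"]
    r = params.discount_rate if discount else 0.0
    if r == 0:
        return earnings * k
    v = 1.0 / (1.0 + r)
    annuity = (1.0 - v**k) / (1.0 - v)
    return earnings * v**death_cycle * annuity


def productivity_stream(n_cycles: int, event_cycles, death_cycle, entry_age: int,
                        params: ParameterSet) -> np.ndarray:
    """Undiscounted per-cycle productivity costs for one trajectory.

    Event cycles add the event-year absenteeism/disability cost; a death
    before retirement adds full annual earnings for each year from the death
    age (inclusive) to retirement. The returned array extends past the death
    cycle when lost-earnings years do.
    """
    e = params.econ
    death_age = None if death_cycle is None else entry_age + int(death_cycle)
    extra = 0
    if death_age is not None and death_age < params.retirement_age:
        extra = params.retirement_age - death_age
    out = np.zeros(max(n_cycles, (0 if death_cycle is None else int(death_cycle)) + extra))
    for c in np.atleast_1d(np.asarray(event_cycles, dtype=int)):
        out[c] += e["productivity_event_cost"]
    if extra:
        out[int(death_cycle): int(death_cycle) + extra] += e["avg_annual_earnings"]
    return out


def redistribution_levy(total_extra_weighted: float, weights: np.ndarray,
                        above_150_mask: np.ndarray) -> np.ndarray:
    """Spread the weighted expansion cost increase evenly per weighted person
    across individuals with family income above 150% FPL.

    Returns the per-person levy (same value for every levied person; zero
    elsewhere). Raises ``ZeroDivisionError`` when a positive total must be
    levied but nobody is above 150% FPL.
    """
    weights = np.asarray(weights, dtype=float)
    mask = np.asarray(above_150_mask, dtype=bool)
    levy = np.zeros(weights.shape)
    if total_extra_weighted == 0:
        return levy
    w_above = weights[mask].sum()
    if w_above <= 0:
        raise ZeroDivisionError(
            "no individuals above 150% FPL to bear the expansion cost redistribution"
        )
    levy[mask] = total_extra_weighted / w_above
    return levy
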