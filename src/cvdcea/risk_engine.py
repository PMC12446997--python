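"""Annual per-person transition probabilities for the microsimulation.

Nonfatal/fatal MI and stroke risks come from sex-specific proportional-hazards
equations differentiating event type (Framingham-style), multiplicatively
re-weighted by the ratio of the individual's pooled-cohort-style (ASCVD) risk
to that of an age-sex-matched reference profile — importing the finer race,
blood-pressure, and diabetes gradients while preserving the event-type split.
Risks double for people with a history of CVD. Death from other causes uses an
age-sex mortality table with MI and stroke deaths subtracted from all-cause
rates. All rates are converted to annual probabilities via 1 - exp(-rate).

Every function accepts numpy arrays (or a population DataFrame) and is
vectorised; scalar inputs work too.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CoefficientError, TableRangeError
from .params import EVENTS, SEXES, ParameterSet

logger = logging.getLogger(__name__)

#: combined annual MI+stroke probability is capped here (logged if binding)
EVENT_PROB_CAP = 0.99


def rate_to_probability(rate):
    """Convert an annual event rate to an annual probability, 1 - exp(-rate)."""
    rate = np.asarray(rate, dtype=float)
    if (rate < 0).any():
        raise ValueError("rate must be nonnegative")
    return -np.expm1(-rate)


def _linear_predictor(betas: dict[str, float], age, sbp, on_treatment, total_chol,
                      hdl_chol, smoker, diabetes):
    age = np.asarray(age, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    on_treatment = np.asarray(on_treatment, dtype=bool)
    lp = (
        betas["ln_age"] * np.log(age)
        + np.where(on_treatment, betas["ln_sbp_treated"], betas["ln_sbp_untreated"]) * np.log(sbp)
        + betas["ln_total_chol"] * np.log(np.asarray(total_chol, dtype=float))
        + betas["ln_hdl_chol"] * np.log(np.asarray(hdl_chol, dtype=float))
        + betas["smoker"] * np.asarray(smoker, dtype=float)
        + betas["diabetes"] * np.asarray(diabetes, dtype=float)
    )
    return lp


def _reference_lp(betas: dict[str, float], params: ParameterSet) -> float:
    ref = params.reference_profile
    return float(
        _linear_predictor(
            betas,
            ref["age"],
            ref["sbp"],
            ref["on_htn_treatment"],
            ref["total_chol"],
            ref["hdl_chol"],
            ref["smoker"],
            ref["diabetes"],
        )
    )


def base_cvd_risk(df: pd.DataFrame, params: ParameterSet, age=None):
    """Annual MI and stroke event rates from the sex-specific hazard equations.

    ``rate = -ln(S0_1yr) * exp(LP - LP_ref)`` with the linear predictor centred
    at the configured reference profile. Returns ``(rate_mi, rate_stroke)``.
    """
    n = len(df)
    age = df["age"].to_numpy() if age is None else np.asarray(age)
    rates = {ev: np.zeros(n) for ev in EVENTS}
    sex_arr = df["sex"].to_numpy()
    for sex in SEXES:
        mask = sex_arr == sex
        if not mask.any():
            continue
        for ev in EVENTS:
            key = (sex, ev)
            if key not in params.framingham:
                raise CoefficientError(f"no risk equation for stratum {key}")
            model = params.framingham[key]
            h0 = -np.log(model.baseline_survival)
            lp = _linear_predictor(
                model.betas,
                age[mask],
                df["sbp"].to_numpy()[mask],
                df["on_htn_treatment"].to_numpy()[mask],
                df["total_chol"].to_numpy()[mask],
                df["hdl_chol"].to_numpy()[mask],
                df["smoker"].to_numpy()[mask],
                df["diabetes"].to_numpy()[mask],
            )
            rates[ev][mask] = h0 * np.exp(lp - _reference_lp(model.betas, params))
    return rates["mi"], rates["stroke"]


def _ascvd_table_race(race: np.ndarray) -> np.ndarray:
    # The pooled-cohort equations publish Black and White/other tables; all
    # other groups are evaluated on the White table, standard practice.
    return np.where(np.asarray(race, dtype=object) == "Black", "black", "white")


def ascvd_ten_year_risk(df: pd.DataFrame, params: ParameterSet, age=None,
                        reference: bool = False) -> np.ndarray:
    """10-year ASCVD-style risk, centred per table at the reference profile.

    With ``reference=True`` the individual's risk factors are replaced by the
    reference profile's (race White, stratum-mean factors) while keeping the
    individual's age and sex — the denominator of the weighting ratio.
    """
    n = len(df)
    age = df["age"].to_numpy() if age is None else np.asarray(age)
    ref = params.reference_profile
    if reference:
        sbp = np.full(n, float(ref["sbp"]))
        tc = np.full(n, float(ref["total_chol"]))
        hdl = np.full(n, float(ref["hdl_chol"]))
        smoker = np.full(n, bool(ref["smoker"]))
        diabetes = np.full(n, bool(ref["diabetes"]))
        treated = np.full(n, bool(ref["on_htn_treatment"]))
        table_race = np.full(n, "white", dtype=object)
    else:
        sbp = df["sbp"].to_numpy()
        tc = df["total_chol"].to_numpy()
        hdl = df["hdl_chol"].to_numpy()
        smoker = df["smoker"].to_numpy()
        diabetes = df["diabetes"].to_numpy()
        treated = df["on_htn_treatment"].to_numpy()
        table_race = _ascvd_table_race(df["race_ethnicity"].to_numpy())

    risk = np.zeros(n)
    sex_arr = df["sex"].to_numpy()
    for sex in SEXES:
        for race in ("white", "black"):
            mask = (sex_arr == sex) & (table_race == race)
            if not mask.any():
                continue
            key = (sex, race)
            if key not in params.ascvd:
                raise CoefficientError(f"no ASCVD table for stratum {key}")
            model = params.ascvd[key]
            lp = _linear_predictor(
                model.betas, age[mask], sbp[mask], treated[mask],
                tc[mask], hdl[mask], smoker[mask], diabetes[mask],
            )
            centred = lp - _reference_lp(model.betas, params)
            risk[mask] = 1.0 - model.baseline_survival ** np.exp(centred)
    return risk


def apply_ascvd_weighting(rate_mi, rate_stroke, df: pd.DataFrame,
                          params: ParameterSet, age=None):
    """Scale both event rates by ASCVD(individual) / ASCVD(reference profile)."""
    risk_ind = ascvd_ten_year_risk(df, params, age=age)
    risk_ref = ascvd_ten_year_risk(df, params, age=age, reference=True)
    if (risk_ref <= 0).any():
        raise ZeroDivisionError("reference-profile ASCVD risk of zero; cannot weight")
    ratio = risk_ind / risk_ref
    return np.asarray(rate_mi) * ratio, np.asarray(rate_stroke) * ratio


def history_multiplier(rate_mi, rate_stroke, cvd_history):
    """Double both event rates for individuals with a history of CVD."""
    factor = np.where(np.asarray(cvd_history, dtype=bool), 2.0, 1.0)
    return np.asarray(rate_mi) * factor, np.asarray(rate_stroke) * factor


def fatal_fraction(age, sex, event: str, params: ParameterSet):
    """Age- and sex-specific probability that an event is fatal (logistic in age)."""
    age = np.asarray(age, dtype=float)
    lo, hi = 19, params.max_age
    if ((age < lo) | (age > hi)).any():
        raise TableRangeError(f"age outside [{lo}, {hi}] in fatal_fraction")
    sex_arr = np.asarray(sex, dtype=object)
    out = np.zeros(age.shape if age.shape else (1,))
    age2 = np.atleast_1d(age)
    sex2 = np.atleast_1d(sex_arr)
    if sex2.size == 1 and age2.size > 1:
        sex2 = np.repeat(sex2, age2.size)
    for s in SEXES:
        mask = sex2 == s
        if not mask.any():
            continue
        if (s, event) not in params.fatal:
            raise CoefficientError(f"no fatal-fraction equation for ({s}, {event})")
        a, b = params.fatal[(s, event)]
        z = a + b * age2[mask]
        out[mask] = 1.0 / (1.0 + np.exp(-z))
    return out if np.asarray(age).shape else float(out[0])


def noncvd_death_prob(age, sex, params: ParameterSet):
    """Annual probability of death from causes other than MI or stroke."""
    age = np.asarray(age)
    scalar = age.shape == ()
    age2 = np.atleast_1d(age).astype(int)
    sex2 = np.atleast_1d(np.asarray(sex, dtype=object))
    if sex2.size == 1 and age2.size > 1:
        sex2 = np.repeat(sex2, age2.size)
    out = np.zeros(age2.size)
    for s in SEXES:
        mask = sex2 == s
        if not mask.any():
            continue
        rates = params.residual_mortality(s)
        lo, hi = params._mortality_ages
        a = age2[mask]
        if ((a < lo) | (a > hi)).any():
            raise TableRangeError(f"age outside mortality table range [{lo}, {hi}]")
        out[mask] = rate_to_probability(rates[a - lo])
    return float(out[0]) if scalar else out


def cap_event_probabilities(p_mi: np.ndarray, p_stroke: np.ndarray,
                            warn: bool = True) -> tuple[np.ndarray, np.ndarray, int]:
    """Proportionally rescale so p_mi + p_stroke never exceeds the cap.

    Returns the capped probabilities and the number of individuals for whom
    the cap was binding (logged unless ``warn`` is False; callers running a
    cycle loop aggregate the count and log once).
    """
    total = p_mi + p_stroke
    over = total > EVENT_PROB_CAP
    n_over = int(over.sum())
    if n_over:
        if warn:
            logger.warning(
                "MI+stroke probability cap (%.2f) binding for %d individual(s); rescaled",
                EVENT_PROB_CAP, n_over,
            )
        scale = np.where(over, EVENT_PROB_CAP / total, 1.0)
        p_mi = p_mi * scale
        p_stroke = p_stroke * scale
    return p_mi, p_stroke, n_over


def annual_transition_probs(df: pd.DataFrame, params: ParameterSet,
                            age=None, cvd_history=None,
                            warn_cap: bool = True) -> dict[str, np.ndarray]:
    """All five annual transition probabilities for the cohort at current ages.

    Composition order: base sex-specific risks → ASCVD re-weighting →
    ×2 history multiplier → rate-to-probability conversion. The combined
    MI+stroke probability is capped at ``EVENT_PROB_CAP`` (proportional
    rescale, logged when binding).
    """
    age = df["age"].to_numpy() if age is None else np.asarray(age)
    hist = df["cvd_history"].to_numpy() if cvd_history is None else np.asarray(cvd_history)
    rate_mi, rate_stroke = base_cvd_risk(df, params, age=age)
    rate_mi, rate_stroke = apply_ascvd_weighting(rate_mi, rate_stroke, df, params, age=age)
    rate_mi, rate_stroke = history_multiplier(rate_mi, rate_stroke, hist)
    p_mi, p_stroke, n_capped = cap_event_probabilities(
        rate_to_probability(rate_mi), rate_to_probability(rate_stroke), warn=warn_cap
    )
    sex = df["sex"].to_numpy()
    return {
        "p_noncvd_death": noncvd_death_prob(age, sex, params),
        "p_mi": p_mi,
        "p_stroke": p_stroke,
        "n_capped": n_capped,
        "p_fatal_given_mi": np.asarray(fatal_fraction(age, sex, "mi", params)),
        "p_fatal_given_stroke": np.asarray(fatal_fraction(age, sex, "stroke", params)),
    }
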