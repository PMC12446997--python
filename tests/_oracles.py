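"""Independent naive re-evaluations used as oracles against the vectorised engine.

Everything here is deliberately scalar, plain-Python arithmetic reading the
packaged coefficient CSVs directly, sharing no code path with the package
implementation beyond the data files themselves.
"""
from __future__ import annotations

import math
from importlib import resources

import pandas as pd
import yaml


def _data(name: str) -> pd.DataFrame:
    with resources.files("cvdcea.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def _yaml(name: str) -> dict:
    with resources.files("cvdcea.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def _coef(df: pd.DataFrame, strata: dict, term: str) -> float:
    sub = df
    for col, val in strata.items():
        sub = sub[sub[col] == val]
    return float(sub[sub["term"] == term]["value"].iloc[0])


def _lp(df: pd.DataFrame, strata: dict, age, sbp, treated, tc, hdl, smoker, diabetes) -> float:
    sbp_term = "ln_sbp_treated" if treated else "ln_sbp_untreated"
    return (
        _coef(df, strata, "ln_age") * math.log(age)
        + _coef(df, strata, sbp_term) * math.log(sbp)
        + _coef(df, strata, "ln_total_chol") * math.log(tc)
        + _coef(df, strata, "ln_hdl_chol") * math.log(hdl)
        + _coef(df, strata, "smoker") * (1.0 if smoker else 0.0)
        + _coef(df, strata, "diabetes") * (1.0 if diabetes else 0.0)
    )


def naive_transition_probs(person: dict, age: int | None = None,
                           cvd_history: bool | None = None) -> dict[str, float]:
    """Scalar re-evaluation of all five annual transition probabilities."""
    cfg = _yaml("parameters.yaml")
    ref = cfg["reference_profile"]
    fram = _data("framingham.csv")
    ascvd = _data("ascvd.csv")
    fatal = _data("fatal_fraction.csv")
    mort = _data("mortality_synthetic.csv")

    age = person["age"] if age is None else age
    hist = person["cvd_history"] if cvd_history is None else cvd_history
    sex = person["sex"]

    def ref_lp(df, strata):
        return _lp(df, strata, ref["age"], ref["sbp"], ref["on_htn_treatment"],
                   ref["total_chol"], ref["hdl_chol"], ref["smoker"], ref["diabetes"])

    rates = {}
    for event in ("mi", "stroke"):
        strata = {"sex": sex, "event": event}
        s0 = _coef(fram, strata, "baseline_survival_1yr")
        lp = _lp(fram, strata, age, person["sbp"], person["on_htn_treatment"],
                 person["total_chol"], person["hdl_chol"], person["smoker"],
                 person["diabetes"])
        rates[event] = -math.log(s0) * math.exp(lp - ref_lp(fram, strata))

    table_race = "black" if person["race_ethnicity"] == "Black" else "white"

    def ascvd_risk(strata, sbp, treated, tc, hdl, smoker, diabetes):
        s0 = _coef(ascvd, strata, "baseline_survival_10yr")
        lp = _lp(ascvd, strata, age, sbp, treated, tc, hdl, smoker, diabetes)
        return 1.0 - s0 ** math.exp(lp - ref_lp(ascvd, strata))

    risk_ind = ascvd_risk({"sex": sex, "race": table_race}, person["sbp"],
                          person["on_htn_treatment"], person["total_chol"],
                          person["hdl_chol"], person["smoker"], person["diabetes"])
    risk_ref = ascvd_risk({"sex": sex, "race": "white"}, ref["sbp"],
                          ref["on_htn_treatment"], ref["total_chol"],
                          ref["hdl_chol"], ref["smoker"], ref["diabetes"])
    ratio = risk_ind / risk_ref
    mult = 2.0 if hist else 1.0

    p_mi = 1.0 - math.exp(-rates["mi"] * ratio * mult)
    p_stroke = 1.0 - math.exp(-rates["stroke"] * ratio * mult)
    total = p_mi + p_stroke
    if total > 0.99:
        p_mi *= 0.99 / total
        p_stroke *= 0.99 / total

    def fatal_p(event):
        row = fatal[(fatal["sex"] == sex) & (fatal["event"] == event)].iloc[0]
        z = float(row["intercept"]) + float(row["age_slope"]) * age
        return 1.0 / (1.0 + math.exp(-z))

    mrow = mort[(mort["sex"] == sex) & (mort["age"] == age)].iloc[0]
    resid = float(mrow["rate_all_cause"]) - float(mrow["rate_mi"]) - float(mrow["rate_stroke"])
    return {
        "p_noncvd_death": 1.0 - math.exp(-resid),
        "p_mi": p_mi,
        "p_stroke": p_stroke,
        "p_fatal_given_mi": fatal_p("mi"),
        "p_fatal_given_stroke": fatal_p("stroke"),
    }


def naive_cost_utility(person: dict, age: int | None = None,
                       cvd_history: bool | None = None,
                       event: bool = False) -> tuple[float, float]:
    """Scalar re-evaluation of the annual cost/utility prediction equation."""
    cu = _data("cost_utility.csv").set_index("term")
    cfg = _yaml("parameters.yaml")
    age = person["age"] if age is None else age
    hist = person["cvd_history"] if cvd_history is None else cvd_history

    def total(col: str) -> float:
        v = cu.loc["intercept", col]
        v += cu.loc["age_minus45", col] * (age - 45.0)
        v += cu.loc["bmi_minus28", col] * (person["bmi"] - 28.0)
        if person["sex"] == "male":
            v += cu.loc["male", col]
        race = person["race_ethnicity"]
        if race != "White":
            v += cu.loc[f"race_{race}", col]
        if person["income_group"] != "high":
            v += cu.loc[f"income_{person['income_group']}", col]
        if person["education"] != "master_doctorate":
            v += cu.loc[f"edu_{person['education']}", col]
        if hist:
            v += cu.loc["cvd_history", col]
        if event:
            v += cu.loc["event_cycle", col]
        if person["diabetes"]:
            v += cu.loc["diabetes", col]
        if person["smoker"]:
            v += cu.loc["smoker", col]
        return float(v)

    cost = max(total("cost"), 0.0)
    if event:
        cost *= float(cfg["econ"]["event_markup"])
    util = min(max(total("utility"), 0.0), 1.0)
    return cost, util


def hand_trace_states(uniforms, probs_by_person, cycles: int) -> list[list[tuple]]:
    """Enumerate state sequences for constant per-person transition probabilities.

    ``probs_by_person`` is a list of dicts with the five probabilities; returns
    per person a list of (cycle, event, fatal, died_noncvd, history_at_start).
    """
    out = []
    for i, pr in enumerate(probs_by_person):
        hist = pr.get("history", False)
        rows = []
        for t in range(cycles):
            u_d, u_e, u_f = uniforms[i, t, 0], uniforms[i, t, 1], uniforms[i, t, 2]
            if u_d < pr["p_noncvd_death"]:
                rows.append((t, "none", False, True, hist))
                break
            mult = 2.0 if hist else 1.0
            p_mi = 1.0 - (1.0 - pr["p_mi_base"]) ** mult
            p_stroke = 1.0 - (1.0 - pr["p_stroke_base"]) ** mult
            event = "none"
            fatal = False
            if u_e < p_mi:
                event = "mi"
                fatal = u_f < pr["p_fatal_given_mi"]
            elif u_e < p_mi + p_stroke:
                event = "stroke"
                fatal = u_f < pr["p_fatal_given_stroke"]
            rows.append((t, event, fatal, False, hist))
            if fatal:
                break
            if event != "none":
                hist = True
        out.append(rows)
    return out
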