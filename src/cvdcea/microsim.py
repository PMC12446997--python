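"""Closed-cohort annual-cycle Monte Carlo Markov-chain microsimulation.

Both policy arms (Medicaid expansion vs nonexpansion) are simulated over the
same cohort with common random numbers: one uniform draw tensor, indexed by
individual row and cycle, is shared between arms, so with a null intervention
every incremental quantity is exactly zero.

Per cycle and per individual, conditional on first surviving non-CVD death,
a single categorical draw selects MI, stroke, or no event; events are fatal
with an age-sex fatal-fraction probability; survivors carry a history of CVD
(doubled event risk) from the next cycle on. The horizon runs to death or age
85. Medicaid recipients' cost effects stop at 65 (Medicare switch) while
risk-factor effects persist. Half-cycle correction: QALYs, annual costs and
person-years accrue half weight in the entry cycle and the death cycle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from . import econ, risk_engine
from .errors import CvdceaError
from .params import InterventionEffect, ParameterSet
from .synthetic_population import PopulationSample

ARMS = ("nonexpansion", "expansion")
HORIZONS = ("lifetime", "10yr", "to65")


class HealthState(str, Enum):
    NO_CVD = "no_cvd"
    HISTORY_CVD = "history_cvd"
    MI_EVENT = "mi_event"
    STROKE_EVENT = "stroke_event"
    CVD_DEATH = "cvd_death"
    NONCVD_DEATH = "noncvd_death"


@dataclass
class CycleRecord:
    cycle: int
    age: int
    state: HealthState
    event: str  # none | mi | stroke
    fatal: bool
    alive_fraction_for_hcc: float


@dataclass
class Trajectory:
    individual_id: int
    arm: str
    records: list[CycleRecord] = field(default_factory=list)


def apply_intervention(individual: pd.Series, params: ParameterSet,
                       effect: InterventionEffect | None = None) -> pd.Series:
    """One-time SBP / HbA1c reduction for a Medicaid-eligible individual.

    Floors at the physiologic lower bounds; the diabetes flag is re-derived
    from HbA1c against the configured threshold. Raises on an ineligible
    individual (contract error).
    """
    if not bool(individual["medicaid_eligible"]):
        raise CvdceaError("apply_intervention called on a non-eligible individual")
    effect = effect or params.intervention
    out = individual.copy()
    out["sbp"] = max(individual["sbp"] + effect.delta_sbp, params.bounds["sbp"][0])
    out["hba1c"] = max(individual["hba1c"] + effect.delta_hba1c, params.bounds["hba1c"][0])
    out["diabetes"] = out["hba1c"] >= params.diabetes_hba1c_threshold
    return out


def apply_intervention_frame(df: pd.DataFrame, params: ParameterSet,
                             effect: InterventionEffect | None = None) -> pd.DataFrame:
    """Vectorised intervention application to the eligible rows of a cohort."""
    effect = effect or params.intervention
    out = df.copy()
    m = out["medicaid_eligible"].to_numpy(bool)
    out.loc[m, "sbp"] = np.maximum(out.loc[m, "sbp"] + effect.delta_sbp, params.bounds["sbp"][0])
    out.loc[m, "hba1c"] = np.maximum(
        out.loc[m, "hba1c"] + effect.delta_hba1c, params.bounds["hba1c"][0]
    )
    # re-derive diabetes only for treated rows: untreated rows keep their flag
    out.loc[m, "diabetes"] = out.loc[m, "hba1c"] >= params.diabetes_hba1c_threshold
    return out


@dataclass
class ArmResult:
    """Per-person discounted outcomes for one arm (aligned with the cohort rows)."""

    arm: str
    population: pd.DataFrame           # post-intervention cohort actually simulated
    weights: np.ndarray
    qalys: np.ndarray                  # discounted QALYs per person
    hc_base: np.ndarray                # health care at baseline utilisation (incl. event markup)
    hc_extra: np.ndarray               # expansion utilisation increase + preventive care
    admin: np.ndarray                  # programme administration (CVD share)
    oop: np.ndarray                    # out-of-pocket component of hc costs actually paid
    oop_relief: np.ndarray             # recipients' OOP reduction vs nonexpansion
    productivity: np.ndarray
    levy: np.ndarray                   # redistribution borne by >150% FPL (filled by run_pair)
    person_years: np.ndarray
    events: dict[str, np.ndarray]      # nonfatal_mi, fatal_mi, nonfatal_stroke, fatal_stroke
    death_cycle: np.ndarray            # -1 if alive at horizon
    death_age: np.ndarray
    trajectories: list[Trajectory] | None = None

    def __len__(self) -> int:
        return len(self.weights)

    def resource_cost(self, perspective: str = "societal") -> np.ndarray:
        """Real resources consumed; invariant to the OOP/non-OOP split."""
        out = self.hc_base + self.hc_extra + self.admin
        if perspective == "societal":
            out = out + self.productivity
        return out

    def attributed_cost(self, perspective: str = "societal") -> np.ndarray:
        """Incidence view: what each person bears after OOP relief and the levy."""
        out = self.hc_base - self.oop_relief + self.levy
        if perspective == "societal":
            out = out + self.productivity
        return out

    @property
    def cvd_deaths(self) -> np.ndarray:
        return self.events["fatal_mi"] + self.events["fatal_stroke"]


def _horizon_cycles(entry_age: np.ndarray, params: ParameterSet, horizon: str) -> np.ndarray:
    if horizon == "lifetime":
        return params.max_age - entry_age
    if horizon == "10yr":
        return np.minimum(10, params.max_age - entry_age)
    if horizon == "to65":
        return np.maximum(params.medicare_age - entry_age, 0)
    raise CvdceaError(f"unknown horizon {horizon!r}; expected one of {HORIZONS}")


def draw_uniforms(n: int, n_cycles: int, seed_key) -> np.ndarray:
    """Uniform draw tensor (n, n_cycles, 3): non-CVD death, event, fatality.

    ``seed_key`` identifies the replication (never the arm); row ``i`` is the
    stream of individual ``i``, which is what makes the arms share randomness.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    return rng.random((n, n_cycles, 3))


def _empty_result(arm: str, df: pd.DataFrame) -> ArmResult:
    z = np.zeros(0)
    return ArmResult(
        arm=arm, population=df, weights=z, qalys=z, hc_base=z, hc_extra=z,
        admin=z, oop=z, oop_relief=z, productivity=z, levy=z, person_years=z,
        events={k: z for k in ("nonfatal_mi", "fatal_mi", "nonfatal_stroke", "fatal_stroke")},
        death_cycle=z, death_age=z,
    )


def run_arm(sample: PopulationSample, params: ParameterSet, arm: str,
            uniforms: np.ndarray | None = None, seed: int | None = None,
            horizon: str = "lifetime", record_trajectories: bool = False) -> ArmResult:
    """Simulate one arm over the whole cohort.

    Pass the same ``uniforms`` tensor to both arms for common random numbers
    (``run_pair`` does this); alternatively pass ``seed`` and the tensor is
    drawn internally with an arm-independent key.
    """
    if arm not in ARMS:
        raise CvdceaError(f"unknown arm {arm!r}")
    base_df = sample.individuals.reset_index(drop=True)
    n = len(base_df)
    if n == 0:
        return _empty_result(arm, base_df)

    df = apply_intervention_frame(base_df, params) if arm == "expansion" else base_df
    entry_age = df["age"].to_numpy(int)
    cycles_i = _horizon_cycles(entry_age, params, horizon)
    t_max = int(cycles_i.max()) if len(cycles_i) else 0
    if uniforms is None:
        if seed is None:
            raise CvdceaError("run_arm needs either a uniforms tensor or a seed")
        uniforms = draw_uniforms(n, t_max, [int(seed)])
    if uniforms.shape[0] != n or uniforms.shape[1] < t_max or uniforms.shape[2] != 3:
        raise CvdceaError(
            f"uniforms tensor shape {uniforms.shape} incompatible with (n={n}, T={t_max}, 3)"
        )

    e = params.econ
    r = params.discount_rate
    recipients = df["medicaid_eligible"].to_numpy(bool) if arm == "expansion" else np.zeros(n, bool)
    m_util = e["expansion_cost_multiplier"]
    admin_amt = e["admin_cost_per_enrollee"] * e["admin_cvd_share"]
    s_unins = e["oop_share_uninsured"]
    s_med = e["oop_share_medicaid"]
    base_oop_share = econ.oop_share(df["insured"].to_numpy(bool), False, params)

    static = econ.static_linear_predictors(df, params)
    alive = np.ones(n, bool)
    hist = df["cvd_history"].to_numpy(bool).copy()
    acc = {k: np.zeros(n) for k in (
        "qalys", "hc_base", "hc_extra", "admin", "oop", "oop_relief", "productivity",
        "person_years",
    )}
    counts = {k: np.zeros(n) for k in ("nonfatal_mi", "fatal_mi", "nonfatal_stroke", "fatal_stroke")}
    death_cycle = np.full(n, -1, dtype=int)
    death_age = np.full(n, -1, dtype=int)
    rec_states: list[tuple] | None = [] if record_trajectories else None

    n_capped_total = 0
    for t in range(t_max):
        active = alive & (t < cycles_i)
        if not active.any():
            break
        age_t = np.minimum(entry_age + t, params.max_age - 1)
        probs = risk_engine.annual_transition_probs(
            df, params, age=age_t, cvd_history=hist, warn_cap=False
        )
        n_capped_total += probs["n_capped"]
        u_d = uniforms[:, t, 0]
        u_e = uniforms[:, t, 1]
        u_f = uniforms[:, t, 2]
        d_nc = active & (u_d < probs["p_noncvd_death"])
        surv = active & ~d_nc
        mi = surv & (u_e < probs["p_mi"])
        stroke = surv & ~mi & (u_e < probs["p_mi"] + probs["p_stroke"])
        f_mi = mi & (u_f < probs["p_fatal_given_mi"])
        f_st = stroke & (u_f < probs["p_fatal_given_stroke"])
        died = d_nc | f_mi | f_st
        event = mi | stroke

        w = np.where(died | (t == 0), 0.5, 1.0) * active
        disc = (1.0 + r) ** (-t)
        acc["person_years"] += w

        cost, util = econ.annual_cost_utility(
            df, params, age=age_t, cvd_history=hist, event=event, static=static
        )
        acc["qalys"] += w * disc * util
        acc["hc_base"] += w * disc * cost * active

        rec_now = recipients & active & (entry_age + t < params.medicare_age)
        extra = ((m_util - 1.0) * cost + e["preventive_cost"]) * rec_now
        acc["hc_extra"] += w * disc * extra
        acc["admin"] += w * disc * admin_amt * rec_now
        oop_now = np.where(rec_now, s_med * (m_util * cost), base_oop_share * cost) * active
        acc["oop"] += w * disc * oop_now
        relief = (s_unins * cost - s_med * (m_util * cost)) * rec_now
        acc["oop_relief"] += w * disc * relief

        acc["productivity"] += disc * e["productivity_event_cost"] * event
        early = died & (entry_age + t < params.retirement_age)
        if early.any():
            acc["productivity"][early] += econ.lost_earnings_present_value(
                entry_age[early] + t, t, params
            )

        counts["nonfatal_mi"] += mi & ~f_mi
        counts["fatal_mi"] += f_mi
        counts["nonfatal_stroke"] += stroke & ~f_st
        counts["fatal_stroke"] += f_st

        if rec_states is not None:
            state = np.full(n, HealthState.NO_CVD.value, dtype=object)
            state[hist] = HealthState.HISTORY_CVD.value
            state[d_nc] = HealthState.NONCVD_DEATH.value
            state[mi] = HealthState.MI_EVENT.value
            state[stroke] = HealthState.STROKE_EVENT.value
            state[f_mi | f_st] = HealthState.CVD_DEATH.value
            rec_states.append((t, entry_age + t, active.copy(), state,
                               np.where(mi, "mi", np.where(stroke, "stroke", "none")),
                               died.copy(), w.copy()))

        hist = hist | (event & ~died)
        death_cycle[died] = t
        death_age[died] = entry_age[died] + t
        alive &= ~died

    if n_capped_total:
        logging.getLogger(__name__).warning(
            "%s arm: MI+stroke probability cap binding in %d person-cycle(s)",
            arm, n_capped_total,
        )

    trajectories = None
    if rec_states is not None:
        ids = df["id"].to_numpy()
        trajectories = []
        for i in range(n):
            tr = Trajectory(individual_id=int(ids[i]), arm=arm)
            for (t, ages, active, state, ev, died, w) in rec_states:
                if not active[i]:
                    continue
                tr.records.append(CycleRecord(
                    cycle=t, age=int(ages[i]), state=HealthState(state[i]),
                    event=str(ev[i]), fatal=bool(died[i] and ev[i] != "none") or
                    (bool(died[i]) and state[i] == HealthState.NONCVD_DEATH),
                    alive_fraction_for_hcc=float(w[i]),
                ))
            trajectories.append(tr)

    return ArmResult(
        arm=arm, population=df, weights=df["weight"].to_numpy(float),
        qalys=acc["qalys"], hc_base=acc["hc_base"], hc_extra=acc["hc_extra"],
        admin=acc["admin"], oop=acc["oop"], oop_relief=acc["oop_relief"],
        productivity=acc["productivity"], levy=np.zeros(n),
        person_years=acc["person_years"], events=counts,
        death_cycle=death_cycle, death_age=death_age, trajectories=trajectories,
    )


def run_pair(sample: PopulationSample, params: ParameterSet, seed_key,
             horizon: str = "lifetime") -> tuple[ArmResult, ArmResult]:
    """Run both arms under common random numbers and apply the redistribution.

    ``seed_key`` is an int or list of ints naming the replication; the arm
    never enters the key.
    """
    df = sample.individuals
    n = len(df)
    if n == 0:
        return _empty_result("nonexpansion", df), _empty_result("expansion", df)
    entry_age = df["age"].to_numpy(int)
    t_max = int(_horizon_cycles(entry_age, params, horizon).max())
    key = [int(seed_key)] if np.isscalar(seed_key) else [int(k) for k in seed_key]
    uniforms = draw_uniforms(n, t_max, key)
    nonexp = run_arm(sample, params, "nonexpansion", uniforms=uniforms, horizon=horizon)
    exp = run_arm(sample, params, "expansion", uniforms=uniforms, horizon=horizon)

    total_extra = float(np.sum(exp.weights * (exp.hc_extra + exp.admin)))
    above = df["income_group"].isin(params.income_above_150).to_numpy()
    exp.levy = econ.redistribution_levy(total_extra, exp.weights, above)
    return nonexp, exp


def simulate_individual(individual: pd.Series, params: ParameterSet, arm: str,
                        seed_key, horizon: str = "lifetime") -> Trajectory:
    """Trajectory of a single person (thin wrapper over the cohort engine)."""
    df = individual.to_frame().T.reset_index(drop=True)
    df = df.astype({c: bool for c in (
        "insured", "medicaid_eligible", "diabetes", "smoker", "on_htn_treatment", "cvd_history"
    )})
    df["age"] = df["age"].astype(int)
    for c in ("sbp", "total_chol", "hdl_chol", "hba1c", "bmi", "weight"):
        df[c] = df[c].astype(float)
    sample = PopulationSample(df, pop_scale=float(df["weight"].sum()))
    entry_age = df["age"].to_numpy(int)
    t_max = int(_horizon_cycles(entry_age, params, horizon).max())
    key = [int(seed_key)] if np.isscalar(seed_key) else [int(k) for k in seed_key]
    uniforms = draw_uniforms(1, t_max, key)
    result = run_arm(sample, params, arm, uniforms=uniforms, horizon=horizon,
                     record_trajectories=True)
    return result.trajectories[0]


def incidence_rates(result: ArmResult, mask: np.ndarray | None = None) -> dict[str, float]:
    """Weighted event rates per 100,000 person-years: nonfatal MI, nonfatal
    stroke (deaths excluded from those numerators), and CVD death."""
    if len(result) == 0:
        raise CvdceaError("incidence undefined for an empty result")
    sel = np.ones(len(result), bool) if mask is None else np.asarray(mask, bool)
    w = result.weights[sel]
    py = float(np.sum(w * result.person_years[sel]))
    if py <= 0:
        raise CvdceaError("incidence undefined: zero person-years")
    def rate(x: np.ndarray) -> float:
        return float(np.sum(w * x[sel]) / py * 1e5)
    return {
        "mi": rate(result.events["nonfatal_mi"]),
        "stroke": rate(result.events["nonfatal_stroke"]),
        "cvd_death": rate(result.cvd_deaths),
        "person_years": py,
    }


def trajectories_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format export of recorded trajectories (id, arm, cycle, age, state, event, fatal)."""
    rows = [
        (tr.individual_id, tr.arm, rec.cycle, rec.age, rec.state.value, rec.event, rec.fatal)
        for tr in trajectories for rec in tr.records
    ]
    return pd.DataFrame(rows, columns=["id", "arm", "cycle", "age", "state", "event", "fatal"])
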