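"""Distributional cost-effectiveness: net health benefit, Atkinson equity metrics.

Cost-effectiveness is summarised as (incremental) net health benefit,
NHB = effects − costs/λ, in QALYs at willingness-to-pay λ. Equity is measured
on the distribution of mean net health across equity-relevant subgroups
(family income, education, race/ethnicity) via the Atkinson social welfare
function: the equally distributed equivalent of health (EDEH) at inequality
aversion ε, the Atkinson index Aε = 1 − EDEH/NHB, the population-scale
inequality burden, and the equity-efficiency plane.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import CvdceaError
from .microsim import ArmResult
from .params import EDUCATION_GROUPS, INCOME_GROUPS, RACES, ParameterSet

logger = logging.getLogger(__name__)

PARTITIONS: dict[str, tuple[str, ...]] = {
    "income_group": INCOME_GROUPS,
    "education": EDUCATION_GROUPS,
    "race_ethnicity": RACES,
}


def net_health_benefit(cost_pp: float, qalys_pp: float, wtp: float):
    """NHB = QALYs − cost/λ (per person, QALY units)."""
    if wtp <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return np.asarray(qalys_pp) - np.asarray(cost_pp) / wtp


def incremental_net_health_benefit(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """INHB = ΔE − ΔC/λ."""
    return float(net_health_benefit(delta_cost, delta_effect, wtp))


def atkinson_ede(health, weights, epsilon: float) -> float:
    """Equally distributed equivalent of a health distribution.

    For ε ≠ 1: (Σ wᵢ hᵢ^(1−ε))^(1/(1−ε)); for ε = 1: exp(Σ wᵢ ln hᵢ).
    Requires strictly positive health values and weights summing to 1.
    """
    h = np.asarray(health, dtype=float)
    w = np.asarray(weights, dtype=float)
    if epsilon < 0:
        raise ValueError("inequality aversion must be nonnegative")
    if (h <= 0).any():
        raise ValueError("Atkinson EDE is undefined for non-positive health values")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
    if epsilon == 1.0:
        return float(np.exp(np.sum(w * np.log(h))))
    p = 1.0 - epsilon
    return float(np.sum(w * h**p) ** (1.0 / p))


def atkinson_index(edeh: float, nhb: float) -> float:
    """Aε = 1 − EDEH/NHB ∈ [0, 1) for positive NHB; NaN (with a diagnostic)
    when mean net health is non-positive, where the decomposition is undefined."""
    if nhb <= 0:
        logger.warning("Atkinson index undefined: mean net health %.4g <= 0", nhb)
        return float("nan")
    return 1.0 - edeh / nhb


def inequality_burden_change(nhb_nonexp: float, edeh_nonexp: float,
                             nhb_exp: float, edeh_exp: float,
                             population_n: float) -> float:
    """Change in the population inequality burden, (Aε·NHB)ₙ − (Aε·NHB)ₑ scaled
    by the population; positive values are equity enhancing.

    Aε·NHB = NHB − EDEH, so the per-person change is
    (NHB − EDEH)_nonexpansion − (NHB − EDEH)_expansion.
    """
    return ((nhb_nonexp - edeh_nonexp) - (nhb_exp - edeh_exp)) * population_n


def equity_efficiency_point(inhb_pp: float, iedeh_pp: float,
                            population_n: float) -> dict[str, float | str]:
    """Coordinates on the equity-efficiency plane.

    y: population INHB (efficiency); x: excess welfare from redistribution,
    (IEDEH − INHB) × population. Quadrant labels follow the plane semantics
    (e.g. bottom-right: not cost-effective but equity enhancing).
    """
    y = inhb_pp * population_n
    x = (iedeh_pp - inhb_pp) * population_n
    if inhb_pp > 0:
        quadrant = "top-right" if iedeh_pp > inhb_pp else "top-left"
    else:
        quadrant = "bottom-right" if iedeh_pp > inhb_pp else "bottom-left"
    return {"x": x, "y": y, "quadrant": quadrant}


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(x * w) / np.sum(w))


@dataclass
class DceaResult:
    """Base-case DCEA summary: totals, special subgroups, and per-partition equity."""

    wtp: float
    epsilon: float
    population_n: float
    totals: dict[str, float]
    subgroups: pd.DataFrame                      # per-group ΔC, ΔE, INHB, fraction
    equity: dict[str, dict[str, float]] = field(default_factory=dict)
    group_nhb: dict[str, pd.DataFrame] = field(default_factory=dict)


def _group_rows(nonexp: ArmResult, exp: ArmResult, params: ParameterSet,
                wtp: float, masks: dict[str, np.ndarray],
                partition: str) -> list[dict]:
    w = nonexp.weights
    w_all = w.sum()
    cost_n = nonexp.attributed_cost(params.perspective)
    cost_e = exp.attributed_cost(params.perspective)
    rows = []
    for label, mask in masks.items():
        if not mask.any():
            rows.append({"partition": partition, "group": label, "fraction": 0.0,
                         "delta_cost": np.nan, "delta_qalys": np.nan, "inhb": np.nan,
                         "cost_nonexp": np.nan, "cost_exp": np.nan,
                         "qalys_nonexp": np.nan, "qalys_exp": np.nan})
            continue
        wg = w[mask]
        c_n = _weighted_mean(cost_n[mask], wg)
        c_e = _weighted_mean(cost_e[mask], wg)
        q_n = _weighted_mean(nonexp.qalys[mask], wg)
        q_e = _weighted_mean(exp.qalys[mask], wg)
        rows.append({
            "partition": partition, "group": label, "fraction": float(wg.sum() / w_all),
            "delta_cost": c_e - c_n, "delta_qalys": q_e - q_n,
            "inhb": incremental_net_health_benefit(c_e - c_n, q_e - q_n, wtp),
            "cost_nonexp": c_n, "cost_exp": c_e, "qalys_nonexp": q_n, "qalys_exp": q_e,
        })
    return rows


def dcea_summary(nonexp: ArmResult, exp: ArmResult, params: ParameterSet,
                 wtp: float | None = None, epsilon: float | None = None) -> DceaResult:
    """Full base-case DCEA over a simulated arm pair.

    Totals and special subgroups (Medicaid-eligible only, history of CVD),
    per-partition group incrementals, and per-partition Atkinson equity
    metrics computed on group mean net health weighted by population fraction.
    """
    wtp = params.wtp if wtp is None else wtp
    epsilon = params.epsilon if epsilon is None else epsilon
    if len(nonexp) == 0:
        return DceaResult(wtp, epsilon, params.population_n, totals={},
                          subgroups=pd.DataFrame(
                              columns=["partition", "group", "fraction", "delta_cost",
                                       "delta_qalys", "inhb"]))
    df = nonexp.population
    all_rows: list[dict] = []
    special = {
        "Total": np.ones(len(df), bool),
        "Medicaid eligible only": df["medicaid_eligible"].to_numpy(bool),
        "History of CVD": df["cvd_history"].to_numpy(bool),
    }
    all_rows += _group_rows(nonexp, exp, params, wtp, special, "special")
    for partition, groups in PARTITIONS.items():
        masks = {g: (df[partition] == g).to_numpy() for g in groups}
        all_rows += _group_rows(nonexp, exp, params, wtp, masks, partition)
    subgroups = pd.DataFrame(all_rows)

    total_row = subgroups[subgroups["group"] == "Total"].iloc[0]
    totals = {
        "cost_nonexp": total_row["cost_nonexp"], "cost_exp": total_row["cost_exp"],
        "qalys_nonexp": total_row["qalys_nonexp"], "qalys_exp": total_row["qalys_exp"],
        "delta_cost": total_row["delta_cost"], "delta_qalys": total_row["delta_qalys"],
        "inhb": total_row["inhb"],
    }

    result = DceaResult(wtp, epsilon, params.population_n, totals, subgroups)
    for partition in PARTITIONS:
        sub = subgroups[(subgroups["partition"] == partition) & (subgroups["fraction"] > 0)]
        gw = sub["fraction"].to_numpy()
        gw = gw / gw.sum()
        nhb_n = net_health_benefit(sub["cost_nonexp"].to_numpy(), sub["qalys_nonexp"].to_numpy(), wtp)
        nhb_e = net_health_benefit(sub["cost_exp"].to_numpy(), sub["qalys_exp"].to_numpy(), wtp)
        result.group_nhb[partition] = pd.DataFrame(
            {"group": sub["group"], "fraction": gw, "nhb_nonexp": nhb_n, "nhb_exp": nhb_e}
        )
        result.equity[partition] = equity_metrics(nhb_n, nhb_e, gw, epsilon,
                                                  params.population_n)
        result.equity[partition]["inhb_pp"] = totals["inhb"]
        point = equity_efficiency_point(totals["inhb"],
                                        result.equity[partition]["iedeh"],
                                        params.population_n)
        result.equity[partition].update(
            {"plane_x": point["x"], "plane_y": point["y"], "quadrant": point["quadrant"]}
        )
    return result


def equity_metrics(nhb_nonexp, nhb_exp, fractions, epsilon: float,
                   population_n: float) -> dict[str, float]:
    """EDEH per arm, IEDEH, Atkinson indices and the inequality-burden change
    for one partition's per-group mean net health."""
    nhb_nonexp = np.asarray(nhb_nonexp, float)
    nhb_exp = np.asarray(nhb_exp, float)
    fractions = np.asarray(fractions, float)
    mean_n = float(np.sum(fractions * nhb_nonexp))
    mean_e = float(np.sum(fractions * nhb_exp))
    edeh_n = atkinson_ede(nhb_nonexp, fractions, epsilon)
    edeh_e = atkinson_ede(nhb_exp, fractions, epsilon)
    return {
        "epsilon": epsilon,
        "nhb_nonexp": mean_n, "nhb_exp": mean_e,
        "edeh_nonexp": edeh_n, "edeh_exp": edeh_e,
        "iedeh": edeh_e - edeh_n,
        "atkinson_nonexp": atkinson_index(edeh_n, mean_n),
        "atkinson_exp": atkinson_index(edeh_e, mean_e),
        "burden_change": inequality_burden_change(mean_n, edeh_n, mean_e, edeh_e,
                                                  population_n),
    }


def breakeven_epsilon(nhb_nonexp, nhb_exp, fractions,
                      bracket: tuple[float, float] = (0.0, 20.0),
                      tol: float = 1e-4) -> float | None:
    """Inequality aversion at which expansion becomes welfare enhancing.

    Bisects IEDEH(ε) = 0 over the bracket; returns None when IEDEH does not
    change sign in range.
    """
    def iedeh(eps: float) -> float:
        return atkinson_ede(nhb_exp, fractions, eps) - atkinson_ede(nhb_nonexp, fractions, eps)

    lo, hi = bracket
    f_lo, f_hi = iedeh(lo), iedeh(hi)
    if f_lo == 0:
        return lo
    if f_lo * f_hi > 0:
        return None
    return float(optimize.brentq(iedeh, lo, hi, xtol=tol))
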