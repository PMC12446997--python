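"""Replication machinery: bootstrap × imputation loops, PSA, CEAC, DSA, pooling.

Probabilistic sensitivity analysis draws one parameter vector per replication
(normal for intervention effects from their 95% CIs, gamma for cost
parameters, beta for the utility intercept — declared, overridable defaults),
resamples the cohort with replacement, and runs both arms under common random
numbers. Pooling across imputations uses Rubin's rules; replication spread is
summarised with Monte Carlo standard errors.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from . import dcea as dcea_mod
from .microsim import run_pair
from .params import ParameterSet
from .synthetic_population import PopulationSample

logger = logging.getLogger(__name__)

#: CI half-width divisor for a normal 95% interval
Z95 = 1.959964

#: parameters that feed transition probabilities — excluded from the ±20% sweep
EXCLUDED_FROM_DSA = frozenset({
    "delta_sbp", "delta_hba1c", "framingham", "ascvd", "fatal_fraction", "mortality",
})

#: default one-way sweep set (cost/utility side + discount rate)
DEFAULT_DSA_SWEEP = (
    "discount_rate",
    "event_markup",
    "expansion_cost_multiplier",
    "preventive_cost",
    "admin_cost_per_enrollee",
    "admin_cvd_share",
    "avg_annual_earnings",
    "productivity_event_cost",
    "oop_share_uninsured",
    "oop_share_medicaid",
)

#: PSA distribution classes per scalar: (family, spread)
PSA_SPECS: dict[str, tuple[str, float]] = {
    "preventive_cost": ("gamma", 0.2),
    "admin_cost_per_enrollee": ("gamma", 0.2),
    "avg_annual_earnings": ("gamma", 0.1),
    "productivity_event_cost": ("gamma", 0.2),
    "expansion_cost_multiplier": ("gamma_minus1", 0.2),
}


def rubins_rules(estimates, variances) -> tuple[float, float]:
    """Pool point estimates and variances across multiply imputed datasets.

    pooled = mean of estimates; total variance = mean within-imputation
    variance + (1 + 1/M) × between-imputation variance.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m == 0:
        raise ValueError("no estimates to pool")
    if m == 1:
        warnings.warn("Rubin's rules with a single imputation: between-variance is zero")
        return float(est[0]), float(var[0])
    pooled = float(est.mean())
    between = float(est.var(ddof=1))
    total = float(var.mean()) + (1.0 + 1.0 / m) * between
    return pooled, total


def monte_carlo_se(values) -> float:
    """Monte Carlo standard error of the replication mean: SD/√B."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("Monte Carlo SE needs at least two replications")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def ci_to_sd(lower: float, upper: float) -> float:
    """SD implied by a normal 95% CI: (upper − lower) / (2 × 1.959964)."""
    return (upper - lower) / (2.0 * Z95)


def draw_parameters(params: ParameterSet, rng: np.random.Generator,
                    scale: float = 1.0) -> ParameterSet:
    """One PSA parameter vector. ``scale`` multiplies every spread; 0 gives the
    degenerate (point-value) draw used to validate the machinery."""
    iv = params.intervention
    sd_sbp = ci_to_sd(*iv.delta_sbp_ci) * scale
    sd_a1c = ci_to_sd(*iv.delta_hba1c_ci) * scale
    new = params.with_intervention(
        rng.normal(iv.delta_sbp, sd_sbp) if sd_sbp > 0 else iv.delta_sbp,
        rng.normal(iv.delta_hba1c, sd_a1c) if sd_a1c > 0 else iv.delta_hba1c,
    )
    for name, (family, spread) in PSA_SPECS.items():
        point = new.econ[name]
        cv = spread * scale
        if cv <= 0:
            continue
        if family == "gamma":
            shape = 1.0 / cv**2
            value = rng.gamma(shape, point / shape) if point > 0 else point
        elif family == "gamma_minus1":
            base = point - 1.0
            shape = 1.0 / cv**2
            value = 1.0 + (rng.gamma(shape, base / shape) if base > 0 else base)
        else:  # pragma: no cover - config guard
            raise ValueError(f"unknown PSA family {family!r}")
        new = new.with_scalar(name, value)
    # utility intercept: beta with matched mean/sd
    u0 = new.utility_coefs["intercept"]
    sd_u = 0.02 * scale
    if sd_u > 0 and 0 < u0 < 1:
        var = sd_u**2
        nu = u0 * (1 - u0) / var - 1.0
        if nu > 0:
            new.utility_coefs["intercept"] = float(rng.beta(u0 * nu, (1 - u0) * nu))
    return new


def run_psa(samples: list[PopulationSample], params: ParameterSet, n_boot: int,
            seed: int, horizon: str = "lifetime", psa_scale: float = 1.0,
            bootstrap: bool = True) -> pd.DataFrame:
    """Bootstrap × imputation replication loop.

    Per replication: resample individuals with replacement, draw one parameter
    vector, run both arms under common random numbers, and record the
    subgroup-level incremental summary. Returns one long DataFrame with
    ``imputation`` and ``replication`` columns prepended to the
    :func:`cvdcea.dcea.dcea_summary` subgroup table.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    frames = []
    for sample in samples:
        imp = sample.imputation_id
        for b in range(n_boot):
            res_rng = np.random.default_rng(np.random.SeedSequence([seed, imp, b, 1]))
            par_rng = np.random.default_rng(np.random.SeedSequence([seed, imp, b, 2]))
            df = sample.individuals
            if bootstrap and len(df):
                idx = res_rng.integers(0, len(df), len(df))
                boot_df = df.iloc[idx].reset_index(drop=True)
                boot_df["id"] = np.arange(len(boot_df))
                boot = PopulationSample(boot_df, imputation_id=imp, pop_scale=sample.pop_scale)
            else:
                boot = sample
            rep_params = draw_parameters(params, par_rng, scale=psa_scale)
            nonexp, exp = run_pair(boot, rep_params, [seed, imp, b, 3], horizon=horizon)
            summary = dcea_mod.dcea_summary(nonexp, exp, rep_params)
            sub = summary.subgroups.copy()
            sub.insert(0, "replication", b)
            sub.insert(0, "imputation", imp)
            frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def _total_rows(replications: pd.DataFrame) -> pd.DataFrame:
    return replications[replications["group"] == "Total"]


def ceac(replications: pd.DataFrame, lambda_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(INHB > 0) at each λ.

    At λ = 0 the limit criterion is a pure cost comparison (ΔC < 0).
    """
    tot = _total_rows(replications)
    dc = tot["delta_cost"].to_numpy()
    de = tot["delta_qalys"].to_numpy()
    rows = []
    for lam in np.asarray(lambda_grid, dtype=float):
        if lam == 0:
            p = float(np.mean((dc < 0) | ((dc == 0) & (de > 0))))
        else:
            p = float(np.mean(de - dc / lam > 0))
        rows.append({"wtp": lam, "p_cost_effective": p})
    return pd.DataFrame(rows)


def dcea_psa(replications: pd.DataFrame, wtp: float, epsilon: float) -> pd.DataFrame:
    """Per-partition quadrant probabilities on the equity-efficiency plane.

    For each replication: INHB from the Total row, IEDEH from the partition's
    group rows at (λ, ε). The four quadrant probabilities sum to one.
    """
    tot = _total_rows(replications).set_index(["imputation", "replication"])
    inhb = (tot["delta_qalys"] - tot["delta_cost"] / wtp)
    rows = []
    for partition in dcea_mod.PARTITIONS:
        part = replications[replications["partition"] == partition]
        quad = {"top-right": 0, "top-left": 0, "bottom-right": 0, "bottom-left": 0}
        n_rep = 0
        for key, grp in part.groupby(["imputation", "replication"]):
            grp = grp[grp["fraction"] > 0]
            gw = grp["fraction"].to_numpy()
            gw = gw / gw.sum()
            nhb_n = dcea_mod.net_health_benefit(
                grp["cost_nonexp"].to_numpy(), grp["qalys_nonexp"].to_numpy(), wtp)
            nhb_e = dcea_mod.net_health_benefit(
                grp["cost_exp"].to_numpy(), grp["qalys_exp"].to_numpy(), wtp)
            iedeh = (dcea_mod.atkinson_ede(nhb_e, gw, epsilon)
                     - dcea_mod.atkinson_ede(nhb_n, gw, epsilon))
            i = float(inhb.loc[key])
            if i > 0:
                quad["top-right" if iedeh > i else "top-left"] += 1
            else:
                quad["bottom-right" if iedeh > i else "bottom-left"] += 1
            n_rep += 1
        for q, c in quad.items():
            rows.append({"partition": partition, "quadrant": q,
                         "probability": c / n_rep if n_rep else float("nan")})
    return pd.DataFrame(rows)


def dsa_tornado(sample: PopulationSample, params: ParameterSet, seed: int,
                sweep: tuple[str, ...] = DEFAULT_DSA_SWEEP, rel: float = 0.2,
                horizon: str = "lifetime") -> pd.DataFrame:
    """One-way deterministic sensitivity: INHB at ±20% of each swept parameter.

    Parameters that affect transition probabilities are excluded (logged).
    Rows are sorted by |INHB range| descending, ready for a tornado diagram.
    """
    def run_inhb(p: ParameterSet) -> float:
        nonexp, exp = run_pair(sample, p, [seed], horizon=horizon)
        return dcea_mod.dcea_summary(nonexp, exp, p).totals["inhb"]

    base_inhb = run_inhb(params)
    rows = []
    for name in sweep:
        if name in EXCLUDED_FROM_DSA:
            logger.warning("parameter %r affects transition probabilities; excluded from DSA",
                           name)
            continue
        base_v = params.econ.get(name, getattr(params, name, None))
        lo_v, hi_v = base_v * (1 - rel), base_v * (1 + rel)
        inhb_lo = run_inhb(params.with_scalar(name, lo_v))
        inhb_hi = run_inhb(params.with_scalar(name, hi_v))
        rows.append({
            "parameter": name, "base_value": base_v, "low_value": lo_v, "high_value": hi_v,
            "inhb_base": base_inhb, "inhb_low": inhb_lo, "inhb_high": inhb_hi,
            "range": abs(inhb_hi - inhb_lo),
        })
    out = pd.DataFrame(rows)
    return out.sort_values("range", ascending=False, ignore_index=True)
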