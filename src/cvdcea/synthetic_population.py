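"""Synthetic person-level population generator and loader.

Emulates the schema and marginal structure of a national fasting-subsample
survey of US adults aged 19-64: demographics, socioeconomic strata,
insurance, CVD risk factors, baseline CVD history, and survey weights.
Risk factors co-move through a Gaussian copula with configurable
correlations; Medicaid eligibility is derived (uninsured, aged 19-64,
family income below the 138% FPL bands) so the eligibility invariant holds
by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError, ValidationError
from .params import EDUCATION_GROUPS, INCOME_GROUPS, RACES

SCHEMA_COLUMNS = [
    "id",
    "age",
    "sex",
    "race_ethnicity",
    "income_group",
    "education",
    "insured",
    "medicaid_eligible",
    "sbp",
    "total_chol",
    "hdl_chol",
    "hba1c",
    "diabetes",
    "smoker",
    "bmi",
    "on_htn_treatment",
    "cvd_history",
    "weight",
]

_COPULA_ORDER = ("sbp", "total_chol", "hdl_chol", "hba1c", "bmi")

# physiologic bounds used for generation clipping and load-time validation
DEFAULT_BOUNDS = {
    "sbp": (80.0, 250.0),
    "total_chol": (80.0, 500.0),
    "hdl_chol": (10.0, 150.0),
    "hba1c": (3.0, 15.0),
    "bmi": (12.0, 80.0),
}


@dataclass
class PopulationSample:
    """A person-level table plus the weighted population total it represents."""

    individuals: pd.DataFrame
    imputation_id: int = 1
    pop_scale: float = 189_980_531.0

    def __post_init__(self) -> None:
        if self.pop_scale <= 0:
            raise ValidationError("pop_scale must be positive")
        ids = self.individuals["id"] if "id" in self.individuals else pd.Series(dtype=int)
        if ids.duplicated().any():
            raise ValidationError("individual ids must be unique")

    def __len__(self) -> int:
        return len(self.individuals)

    def weighted_fraction(self, mask: pd.Series | np.ndarray) -> float:
        w = self.individuals["weight"].to_numpy()
        if w.sum() == 0:
            return float("nan")
        return float((w * np.asarray(mask)).sum() / w.sum())


def _normalise_partition(name: str, targets: dict[str, float]) -> dict[str, float]:
    total = float(sum(targets.values()))
    if any(v < 0 for v in targets.values()):
        raise ConfigurationError(f"{name} fractions must be nonnegative")
    # printed survey tables round to 2 dp, so partitions may sum to e.g. 1.01
    if not (0.95 <= total <= 1.05):
        raise ConfigurationError(
            f"{name} fractions sum to {total:.3f}; must be within [0.95, 1.05]"
        )
    return {k: v / total for k, v in targets.items()}


def generate_population(config: dict, seed: int) -> PopulationSample:
    """Generate ``config['n']`` individuals; deterministic given (config, seed).

    Weighted fractions of the configured strata, Medicaid eligibility, and CVD
    history reproduce the (partition-normalised) targets within sampling error
    (within ±0.02 for n ≥ 5,000).
    """
    n = int(config["n"])
    rng = np.random.default_rng(seed)
    frac = config["fractions"]
    income_t = _normalise_partition("income", frac["income"])
    edu_t = _normalise_partition("education", frac["education"])
    race_t = _normalise_partition("race_ethnicity", frac["race_ethnicity"])
    p_eligible = float(frac["medicaid_eligible"])
    p_history = float(frac["cvd_history"])
    below_138 = tuple(config.get("income_below_138", ("poor", "near_poor")))
    mass_below = sum(income_t[g] for g in below_138)
    if p_eligible > mass_below + 1e-12:
        raise ConfigurationError(
            f"medicaid_eligible target {p_eligible} exceeds the income mass below "
            f"138% FPL ({mass_below:.4f})"
        )

    if n == 0:
        empty = pd.DataFrame(columns=SCHEMA_COLUMNS)
        return PopulationSample(empty, imputation_id=1, pop_scale=config.get("pop_scale", 1.0))

    age = rng.integers(int(config["age_min"]), int(config["age_max"]) + 1, size=n)
    sex = np.where(rng.random(n) < float(config["female_fraction"]), "female", "male")

    def _cat(targets: dict[str, float], order: tuple[str, ...]) -> np.ndarray:
        cats = [c for c in order if c in targets]
        p = np.array([targets[c] for c in cats])
        return np.asarray(cats, dtype=object)[rng.choice(len(cats), size=n, p=p / p.sum())]

    income = _cat(income_t, INCOME_GROUPS)
    education = _cat(edu_t, EDUCATION_GROUPS)
    race = _cat(race_t, RACES)

    # Insurance: uninsured probability below 138% FPL is chosen so that
    # P(uninsured AND below 138% FPL) hits the Medicaid-eligible target.
    p_unins_below = p_eligible / mass_below
    is_below = np.isin(income, below_138)
    p_unins = np.where(is_below, p_unins_below, float(config["uninsured_above_fpl"]))
    insured = rng.random(n) >= p_unins
    eligible = (~insured) & is_below  # ages are 19-64 by construction

    # Risk factors via a Gaussian copula, then marginal transforms.
    corr = np.asarray(config["copula_correlation"], dtype=float)
    if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
        raise ConfigurationError("copula_correlation must be a symmetric 5x5 matrix")
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ chol.T
    u = stats.norm.cdf(z)
    rf = {}
    for j, name in enumerate(_COPULA_ORDER):
        spec = config["risk_factors"][name]
        if spec["dist"] == "normal":
            x = stats.norm.ppf(u[:, j], loc=spec["mean"], scale=spec["sd"])
        elif spec["dist"] == "shifted_lognormal":
            x = spec["shift"] + np.exp(stats.norm.ppf(u[:, j], loc=spec["mu"], scale=spec["sigma"]))
        else:
            raise ConfigurationError(f"unknown marginal dist {spec['dist']!r} for {name}")
        lo, hi = DEFAULT_BOUNDS[name]
        rf[name] = np.clip(x, lo, hi)

    threshold = float(config.get("diabetes_hba1c_threshold", 6.5))
    diabetes = rf["hba1c"] >= threshold
    smoker = rng.random(n) < float(config["smoker_fraction"])
    on_tx = rng.random(n) < float(config["htn_treatment_fraction"])
    history = rng.random(n) < p_history

    sigma = float(config.get("weight_sigma", 0.3))
    w = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    pop_scale = float(config.get("pop_scale", 189_980_531.0))
    w = w / w.sum() * pop_scale

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=int),
            "age": age.astype(int),
            "sex": sex,
            "race_ethnicity": race,
            "income_group": income,
            "education": education,
            "insured": insured,
            "medicaid_eligible": eligible,
            "sbp": rf["sbp"],
            "total_chol": rf["total_chol"],
            "hdl_chol": rf["hdl_chol"],
            "hba1c": rf["hba1c"],
            "diabetes": diabetes,
            "smoker": smoker,
            "bmi": rf["bmi"],
            "on_htn_treatment": on_tx,
            "cvd_history": history,
            "weight": w,
        },
        columns=SCHEMA_COLUMNS,
    )
    return PopulationSample(df, imputation_id=1, pop_scale=pop_scale)


def generate_imputation_replicates(config: dict, seed: int, m: int = 10) -> list[PopulationSample]:
    """M perturbed replicates of one population, to exercise Rubin's-rules pooling.

    The generator emits complete data; replicates jitter the continuous risk
    factors slightly (2% of each marginal SD), standing in for between-imputation
    variability without modelling missingness itself.
    """
    base = generate_population(config, seed)
    out = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    for i in range(1, m + 1):
        df = base.individuals.copy()
        if i > 1 and len(df):
            for name in _COPULA_ORDER:
                spec = config["risk_factors"][name]
                sd = spec.get("sd", spec.get("sigma", 0.1))
                lo, hi = DEFAULT_BOUNDS[name]
                df[name] = np.clip(
                    df[name] + rng.normal(0.0, 0.02 * float(sd), size=len(df)), lo, hi
                )
            threshold = float(config.get("diabetes_hba1c_threshold", 6.5))
            df["diabetes"] = df["hba1c"] >= threshold
        out.append(PopulationSample(df, imputation_id=i, pop_scale=base.pop_scale))
    return out


def write_population(sample: PopulationSample, path) -> None:
    sample.individuals.to_csv(path, index=False)


def load_population(path, bounds: dict | None = None, pop_scale: float | None = None) -> PopulationSample:
    """Load and validate a population CSV with the ``Individual`` schema.

    Raises :class:`SchemaError` naming missing columns, or
    :class:`ValidationError` listing the offending rows and bounds.
    """
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"population file missing required column(s): {missing}")
    df = df[SCHEMA_COLUMNS]
    for col in ("insured", "medicaid_eligible", "diabetes", "smoker", "on_htn_treatment", "cvd_history"):
        df[col] = df[col].astype(bool)

    problems: list[str] = []
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for col, (lo, hi) in bounds.items():
        bad = df.index[(df[col] < lo) | (df[col] > hi)].tolist()
        if bad:
            problems.append(f"{col} outside [{lo}, {hi}] in rows {bad}")
    bad_w = df.index[df["weight"] <= 0].tolist()
    if bad_w:
        problems.append(f"weight must be strictly positive; rows {bad_w}")
    bad_age = df.index[(df["age"] < 19) | (df["age"] > 64)].tolist()
    if bad_age:
        problems.append(f"age outside [19, 64] in rows {bad_age}")
    bad_elig = df.index[df["medicaid_eligible"] & df["insured"]].tolist()
    if bad_elig:
        problems.append(f"medicaid_eligible but insured in rows {bad_elig}")
    for col, allowed in (
        ("sex", ("male", "female")),
        ("race_ethnicity", RACES),
        ("income_group", INCOME_GROUPS),
        ("education", EDUCATION_GROUPS),
    ):
        bad = df.index[~df[col].isin(allowed)].tolist()
        if bad:
            problems.append(f"{col} not in {allowed} in rows {bad}")
    if problems:
        raise ValidationError("; ".join(problems))
    scale = pop_scale if pop_scale is not None else float(df["weight"].sum())
    return PopulationSample(df, imputation_id=1, pop_scale=scale)
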