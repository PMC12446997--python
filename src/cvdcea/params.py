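"""Model parameters: coefficient tables, economic scalars, intervention effects.

Every input the simulation consumes lives on a :class:`ParameterSet` so a run is
fully determined by (population sample, parameters, seed). Packaged defaults are
loaded from ``cvdcea/data``; any table or scalar can be overridden, which is how
the deterministic and probabilistic sensitivity analyses perturb the model.
"""
from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import CoefficientError, ConfigurationError

SEXES = ("male", "female")
EVENTS = ("mi", "stroke")
RACES = ("Asian", "Black", "Hispanic", "Other", "White")
INCOME_GROUPS = ("poor", "near_poor", "low", "medium", "high")
EDUCATION_GROUPS = ("no_degree", "ged_hs", "associate_bachelor", "master_doctorate")

#: terms every proportional-hazards risk table must provide
RISK_TERMS = (
    "ln_age",
    "ln_sbp_untreated",
    "ln_sbp_treated",
    "ln_total_chol",
    "ln_hdl_chol",
    "smoker",
    "diabetes",
)


@dataclass(frozen=True)
class InterventionEffect:
    """One-time risk-factor reductions for Medicaid recipients in the expansion arm."""

    delta_sbp: float = -3.03
    delta_sbp_ci: tuple[float, float] = (-5.33, -0.73)
    delta_hba1c: float = -0.14
    delta_hba1c_ci: tuple[float, float] = (-0.24, -0.03)


@dataclass
class HazardModel:
    """Proportional-hazards risk equation: rate = -ln(S0) * exp(LP - LP_ref)."""

    betas: dict[str, float]
    baseline_survival: float

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_survival <= 1.0):
            raise CoefficientError(
                f"baseline survival must be in (0, 1], got {self.baseline_survival}"
            )
        missing = [t for t in RISK_TERMS if t not in self.betas]
        if missing:
            raise CoefficientError(f"risk table missing coefficient(s): {missing}")


@dataclass
class ParameterSet:
    """All model inputs for one run (point values; PSA draws replace scalars)."""

    framingham: dict[tuple[str, str], HazardModel]
    ascvd: dict[tuple[str, str], HazardModel]
    fatal: dict[tuple[str, str], tuple[float, float]]  # (sex, event) -> (intercept, age slope)
    mortality: pd.DataFrame
    cost_coefs: dict[str, float]
    utility_coefs: dict[str, float]
    econ: dict[str, float]
    intervention: InterventionEffect
    reference_profile: dict[str, Any]
    bounds: dict[str, tuple[float, float]]
    income_below_138: tuple[str, ...] = ("poor", "near_poor")
    income_above_150: tuple[str, ...] = ("low", "medium", "high")
    wtp: float = 150_000.0
    epsilon: float = 0.5
    discount_rate: float = 0.03
    max_age: int = 85
    medicare_age: int = 65
    retirement_age: int = 65
    population_n: float = 189_980_531.0
    diabetes_hba1c_threshold: float = 6.5
    perspective: str = "societal"  # or "healthcare"
    # cached per-sex residual non-CVD mortality rates, indexed by age
    _mortality_rates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _mortality_ages: tuple[int, int] = (19, 85)

    def copy(self) -> "ParameterSet":
        new = dataclasses.replace(self)
        new.econ = dict(self.econ)
        new.cost_coefs = dict(self.cost_coefs)
        new.utility_coefs = dict(self.utility_coefs)
        new._mortality_rates = dict(self._mortality_rates)
        return new

    def with_scalar(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one named scalar replaced (econ entries, top-level rates)."""
        new = self.copy()
        if name in new.econ:
            new.econ[name] = value
        elif hasattr(new, name) and isinstance(getattr(new, name), (int, float)):
            setattr(new, name, value)
        else:
            raise ConfigurationError(f"unknown scalar parameter {name!r}")
        return new

    def with_intervention(self, delta_sbp: float, delta_hba1c: float) -> "ParameterSet":
        new = self.copy()
        new.intervention = dataclasses.replace(
            self.intervention, delta_sbp=delta_sbp, delta_hba1c=delta_hba1c
        )
        return new

    # -- mortality -------------------------------------------------------
    def residual_mortality(self, sex: str) -> np.ndarray:
        """Residual (non-CVD) death rate per person-year indexed by age offset.

        Entry ``i`` is the rate at age ``_mortality_ages[0] + i``.
        """
        if sex not in self._mortality_rates:
            from .errors import ValidationError

            sub = self.mortality[self.mortality["sex"] == sex].sort_values("age")
            if sub.empty:
                raise CoefficientError(f"mortality table has no rows for sex={sex!r}")
            resid = (
                sub["rate_all_cause"].to_numpy()
                - sub["rate_mi"].to_numpy()
                - sub["rate_stroke"].to_numpy()
            )
            if (resid < -1e-12).any():
                raise ValidationError(
                    "mortality table violates rate_all_cause >= rate_mi + rate_stroke"
                )
            ages = sub["age"].to_numpy()
            lo, hi = int(ages.min()), int(ages.max())
            if not (np.diff(ages) == 1).all():
                raise ValidationError("mortality table ages must be consecutive")
            self._mortality_rates[sex] = np.maximum(resid, 0.0)
            self._mortality_ages = (lo, hi)
        return self._mortality_rates[sex]


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("cvdcea.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def _read_packaged_yaml(name: str) -> dict:
    with resources.files("cvdcea.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def _hazard_tables(
    df: pd.DataFrame, strata_cols: list[str], survival_term: str
) -> dict[tuple, HazardModel]:
    tables: dict[tuple, HazardModel] = {}
    for key, grp in df.groupby(strata_cols):
        key = tuple(key) if isinstance(key, tuple) else (key,)
        coef = dict(zip(grp["term"], grp["value"]))
        s0 = coef.pop(survival_term, None)
        if s0 is None:
            raise CoefficientError(f"stratum {key} missing {survival_term}")
        tables[key] = HazardModel(betas=coef, baseline_survival=float(s0))
    return tables


def load_parameters(overrides: dict | None = None) -> ParameterSet:
    """Load the packaged default :class:`ParameterSet`, optionally overriding
    top-level scalars / econ entries with a flat ``overrides`` mapping."""
    cfg = _read_packaged_yaml("parameters.yaml")
    fram = _hazard_tables(
        _read_packaged_csv("framingham.csv"), ["sex", "event"], "baseline_survival_1yr"
    )
    ascvd = _hazard_tables(
        _read_packaged_csv("ascvd.csv"), ["sex", "race"], "baseline_survival_10yr"
    )
    fatal_df = _read_packaged_csv("fatal_fraction.csv")
    fatal = {
        (r.sex, r.event): (float(r.intercept), float(r.age_slope))
        for r in fatal_df.itertuples()
    }
    cu = _read_packaged_csv("cost_utility.csv")
    cost_coefs = dict(zip(cu["term"], cu["cost"].astype(float)))
    utility_coefs = dict(zip(cu["term"], cu["utility"].astype(float)))
    iv = cfg["intervention"]
    params = ParameterSet(
        framingham=fram,
        ascvd=ascvd,
        fatal=fatal,
        mortality=_read_packaged_csv("mortality_synthetic.csv"),
        cost_coefs=cost_coefs,
        utility_coefs=utility_coefs,
        econ={k: float(v) for k, v in cfg["econ"].items()},
        intervention=InterventionEffect(
            delta_sbp=iv["delta_sbp"],
            delta_sbp_ci=tuple(iv["delta_sbp_ci"]),
            delta_hba1c=iv["delta_hba1c"],
            delta_hba1c_ci=tuple(iv["delta_hba1c_ci"]),
        ),
        reference_profile=dict(cfg["reference_profile"]),
        bounds={k: tuple(v) for k, v in cfg["bounds"].items()},
        income_below_138=tuple(cfg["income_below_138"]),
        income_above_150=tuple(cfg["income_above_150"]),
        wtp=float(cfg["wtp"]),
        epsilon=float(cfg["epsilon"]),
        discount_rate=float(cfg["discount_rate"]),
        max_age=int(cfg["max_age"]),
        medicare_age=int(cfg["medicare_age"]),
        retirement_age=int(cfg["retirement_age"]),
        population_n=float(cfg["population_n"]),
        diabetes_hba1c_threshold=float(cfg["diabetes_hba1c_threshold"]),
    )
    if overrides:
        for name, value in overrides.items():
            params = params.with_scalar(name, value)
    return params


def default_population_config() -> dict:
    """Packaged default configuration for the synthetic population generator."""
    return copy.deepcopy(_read_packaged_yaml("population_default.yaml"))
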