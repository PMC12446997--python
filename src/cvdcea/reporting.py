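"""Run configuration validation and result tables in the study's reporting shape."""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .dcea import DceaResult
from .errors import ConfigurationError
from .microsim import HORIZONS

logger = logging.getLogger(__name__)

#: subgroup labels in report order, matching the published table strings
GROUP_LABELS: dict[tuple[str, str], str] = {
    ("special", "Total"): "Total",
    ("special", "Medicaid eligible only"): "Medicaid eligible only",
    ("special", "History of CVD"): "History of CVD",
    ("income_group", "high"): "High",
    ("income_group", "medium"): "Medium",
    ("income_group", "low"): "Low",
    ("income_group", "near_poor"): "Near poor",
    ("income_group", "poor"): "Poor",
    ("education", "master_doctorate"): "Master/Doctorate",
    ("education", "associate_bachelor"): "Associate/Bachelor",
    ("education", "ged_hs"): "GED/HS",
    ("education", "no_degree"): "No degree",
    ("race_ethnicity", "Asian"): "Asian",
    ("race_ethnicity", "Black"): "Black",
    ("race_ethnicity", "Hispanic"): "Hispanic",
    ("race_ethnicity", "Other"): "Other race",
    ("race_ethnicity", "White"): "White",
}

MISSING = "—"


def round_half_up(value: float, digits: int) -> float:
    """Decimal half-up rounding (printed tables round 0.00365 up to 0.0037)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return float("nan")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Base-case run settings; defaults are the study's base case."""

    wtp: float = 150_000.0
    epsilon: float = 0.5
    discount_rate: float = 0.03
    horizon: str = "lifetime"
    perspective: str = "societal"
    seed: int = 1
    n: int = 8141
    n_boot: int = 50
    m_imputations: int = 10
    population_n: float = 189_980_531.0

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: dict | None) -> RunConfig:
    """Validate a structured config mapping, fill base-case defaults, and echo
    the effective configuration to the log."""
    config = dict(config or {})
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(config) - known)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    cfg = RunConfig(**config)
    if cfg.wtp <= 0:
        raise ConfigurationError(f"wtp must be positive, got {cfg.wtp}")
    if not (0.0 <= cfg.epsilon <= 30.0):
        raise ConfigurationError(f"epsilon out of range [0, 30]: {cfg.epsilon}")
    if not (0.0 <= cfg.discount_rate < 1.0):
        raise ConfigurationError(f"discount_rate out of range [0, 1): {cfg.discount_rate}")
    if cfg.horizon not in HORIZONS:
        raise ConfigurationError(f"horizon must be one of {HORIZONS}, got {cfg.horizon!r}")
    if cfg.perspective not in ("societal", "healthcare"):
        raise ConfigurationError(f"perspective must be societal|healthcare, got {cfg.perspective!r}")
    if cfg.n < 0 or cfg.n_boot < 1 or cfg.m_imputations < 1:
        raise ConfigurationError("n must be >= 0; n_boot and m_imputations must be >= 1")
    logger.info("effective run configuration: %s", cfg.to_dict())
    return cfg


def build_table1(result: DceaResult) -> pd.DataFrame:
    """Per-person incremental costs, QALYs, INHB and IEDEH by subgroup.

    Rows: Total, Medicaid-eligible only, History of CVD, then each income,
    education and race/ethnicity stratum. Costs round to whole dollars,
    QALY-scale quantities to four decimals; raw unrounded values are kept in
    ``*_raw`` columns. Missing subgroups carry an explicit marker.
    """
    sub = result.subgroups.set_index(["partition", "group"]) if len(result.subgroups) else None
    rows = []
    for (partition, group), label in GROUP_LABELS.items():
        iedeh = result.equity.get(partition, {}).get("iedeh", np.nan)
        if sub is None or (partition, group) not in sub.index:
            rows.append({
                "group": label, "delta_cost": MISSING, "delta_qalys": MISSING,
                "inhb": MISSING, "iedeh": MISSING, "fraction": MISSING,
                "delta_cost_raw": np.nan, "delta_qalys_raw": np.nan,
                "inhb_raw": np.nan, "iedeh_raw": np.nan, "fraction_raw": np.nan,
            })
            continue
        r = sub.loc[(partition, group)]
        present = not (isinstance(r["delta_cost"], float) and np.isnan(r["delta_cost"]))
        rows.append({
            "group": label,
            "delta_cost": round_half_up(r["delta_cost"], 0) if present else MISSING,
            "delta_qalys": round_half_up(r["delta_qalys"], 4) if present else MISSING,
            "inhb": round_half_up(r["inhb"], 4) if present else MISSING,
            "iedeh": round_half_up(iedeh, 4) if partition != "special" else MISSING,
            "fraction": round_half_up(r["fraction"], 2) if present else MISSING,
            "delta_cost_raw": r["delta_cost"], "delta_qalys_raw": r["delta_qalys"],
            "inhb_raw": r["inhb"],
            "iedeh_raw": iedeh if partition != "special" else np.nan,
            "fraction_raw": r["fraction"],
        })
    return pd.DataFrame(rows)
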