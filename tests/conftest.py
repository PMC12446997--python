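import copy

import numpy as np
import pytest

from cvdcea import default_population_config, generate_population, load_parameters
from cvdcea.params import EVENTS, SEXES, HazardModel


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def pop_config():
    return default_population_config()


@pytest.fixture(scope="session")
def small_sample(pop_config):
    cfg = copy.deepcopy(pop_config)
    cfg["n"] = 500
    return generate_population(cfg, seed=7)


def make_forced_params(base, p_mi=0.0, p_stroke=0.0, p_fatal=0.0, p_noncvd=0.0):
    """ParameterSet with constant, hand-chosen transition probabilities.

    All risk coefficients are zeroed so the annual event probability is exactly
    1 - baseline_survival; the fatal fraction is a flat logistic; the mortality
    table carries one constant residual rate.
    """
    new = base.copy()
    zero = {t: 0.0 for t in (
        "ln_age", "ln_sbp_untreated", "ln_sbp_treated", "ln_total_chol",
        "ln_hdl_chol", "smoker", "diabetes",
    )}
    new.framingham = {
        (s, "mi"): HazardModel(dict(zero), 1.0 - p_mi) for s in SEXES
    } | {
        (s, "stroke"): HazardModel(dict(zero), 1.0 - p_stroke) for s in SEXES
    }
    new.ascvd = {(s, r): HazardModel(dict(zero), 0.9) for s in SEXES for r in ("white", "black")}
    if p_fatal <= 0:
        logit = -700.0
    elif p_fatal >= 1:
        logit = 700.0
    else:
        logit = float(np.log(p_fatal / (1.0 - p_fatal)))
    new.fatal = {(s, e): (logit, 0.0) for s in SEXES for e in EVENTS}
    rate = 1e9 if p_noncvd >= 1 else -float(np.log1p(-p_noncvd))
    mort = base.mortality.copy()
    mort["rate_all_cause"] = rate
    mort["rate_mi"] = 0.0
    mort["rate_stroke"] = 0.0
    new.mortality = mort
    new._mortality_rates = {}
    return new


def make_null_cost_params(base):
    """ParameterSet whose expansion arm changes nothing: zero intervention
    effects and zero cost deltas (multiplier 1, no preventive/admin, equal
    OOP shares)."""
    new = base.with_intervention(0.0, 0.0)
    new.econ.update({
        "expansion_cost_multiplier": 1.0,
        "preventive_cost": 0.0,
        "admin_cost_per_enrollee": 0.0,
        "oop_share_medicaid": new.econ["oop_share_uninsured"],
    })
    return new


@pytest.fixture()
def forced_params_factory(params):
    def _make(**kw):
        return make_forced_params(params, **kw)
    return _make


@pytest.fixture()
def null_params(params):
    return make_null_cost_params(params)
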