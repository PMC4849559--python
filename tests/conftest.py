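"""Shared fixtures: ground truth, reference inputs, small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import scadmodel as sm


@pytest.fixture(scope="session")
def gen_config() -> sm.GeneratorConfig:
    return sm.GeneratorConfig()


@pytest.fixture(scope="session")
def truth(gen_config) -> sm.TrueParameters:
    return sm.default_true_parameters(gen_config)


@pytest.fixture(scope="session")
def life_table():
    return sm.synthetic_life_table()


@pytest.fixture(scope="session")
def utilities():
    return sm.synthetic_utility_catalogue()


@pytest.fixture(scope="session")
def truth_equations(truth, life_table):
    return truth.to_equation_set(life_table)


@pytest.fixture(scope="session")
def truth_cost_model(truth):
    return truth.to_cost_model()


@pytest.fixture(scope="session")
def cohort_small(gen_config) -> pd.DataFrame:
    return sm.generate_cohort(300, seed=11, config=gen_config)


@pytest.fixture(scope="session")
def histories_small(cohort_small, truth) -> pd.DataFrame:
    return sm.simulate_event_histories(cohort_small, truth, seed=12)


@pytest.fixture(scope="session")
def profile_63(gen_config) -> pd.Series:
    """A mid-sixties male profile used across engine tests."""
    cohort = sm.generate_cohort(50, seed=21, config=gen_config)
    cohort = cohort.assign(age_entry=63.0)
    return cohort.iloc[0]


def constant_hazard_fit(endpoint: str, rate: float) -> "sm.SurvivalFit":
    """Intercept-only exponential fit with hazard ``rate`` per year."""
    coef = pd.Series({"intercept": -float(np.log(rate))})
    return sm.SurvivalFit(
        endpoint=endpoint, family="exponential", coef=coef, sigma=1.0, q=None,
        vcov=np.zeros((1, 1)), loglik=0.0, n_events=0, n_obs=0,
        fingerprint="const", param_names=["intercept"],
    )


def constant_hazard_equations(
    life_table,
    rates: dict[str, float],
    post_rates: dict[tuple[str, str], float] | None = None,
    splice_time: float = 1e9,
) -> "sm.RiskEquationSet":
    """Equation set with constant cause-specific hazards (life-table splice
    pushed out of the horizon unless requested)."""
    from scadmodel.equations import NONFATAL_EVENTS, POST_CAUSES
    from scadmodel.transitions import PRIMARY_CAUSES

    tiny = 1e-12
    primary = {c: constant_hazard_fit(c, rates.get(c, tiny)) for c in PRIMARY_CAUSES}
    post_rates = post_rates or {}
    post = {
        (e, c): constant_hazard_fit(f"{c}_after_{e}", post_rates.get((e, c), tiny))
        for e in NONFATAL_EVENTS
        for c in POST_CAUSES
    }
    return sm.RiskEquationSet(
        primary=primary, post=post, life_table=life_table, splice_time=splice_time
    )


@pytest.fixture(scope="session")
def zero_covariate_profile() -> pd.Series:
    prof = pd.Series({c: 0.0 for c in sm.COVARIATE_COLUMNS})
    prof["age_entry"] = 40.0
    return prof
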