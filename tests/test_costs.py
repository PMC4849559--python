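"""Cost model estimation and utility catalogue lookups."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import scadmodel as sm
from scadmodel.costs import (
    CostComponent,
    CostModel,
    UtilityCatalogue,
    cost_features,
    cycle_cost,
    cycle_cost_components,
    cycle_utility,
    fit_cost_model,
)
from scadmodel.covariates import design_row


@pytest.fixture(scope="module")
def panel_medium(truth, gen_config):
    cohort = sm.generate_cohort(8000, seed=30, config=gen_config)
    hist = sm.simulate_event_histories(cohort, truth, seed=31)
    panel = sm.simulate_cost_panel(cohort, hist, truth, seed=32)
    return cohort, panel


class TestFitCostModel:
    def test_recovers_truth_coefficients(self, truth, panel_medium):
        cohort, panel = panel_medium
        model = fit_cost_model(panel, cohort)
        cvd = model.components["cvd"]
        for name in ("state_post_mi", "acute", "heart_failure", "current_age"):
            i = list(cvd.coef.index).index(name)
            se = np.sqrt(cvd.vcov[i, i])
            assert abs(cvd.coef[name] - truth.cost["cvd"][name]) < max(3 * se, 0.02), name
        other = model.components["other"]
        for name in ("cancer", "copd"):
            i = list(other.coef.index).index(name)
            se = np.sqrt(other.vcov[i, i])
            assert abs(other.coef[name] - truth.cost["other"][name]) < max(3 * se, 0.02), name

    def test_noiseless_panel_reproduces_observed_costs(self, truth, gen_config):
        cohort = sm.generate_cohort(800, seed=33, config=gen_config)
        hist = sm.simulate_event_histories(cohort, truth, seed=34)
        truth0 = dataclasses.replace(truth, cost_noise_shape=None)
        panel = sm.simulate_cost_panel(cohort, hist, truth0, seed=35)
        model = fit_cost_model(panel, cohort)
        dt = 90.0 / 365.25
        merged = panel.merge(cohort, on="patient_id").head(200)
        for _, row in merged.iterrows():
            x = design_row(cohort[cohort["patient_id"] == row["patient_id"]].iloc[0])
            cse = None if np.isnan(row["cycles_since_event"]) else int(row["cycles_since_event"])
            pred = cycle_cost(model, x, row["state_at_cycle"], cse,
                              row["age_entry"] + row["cycle_index"] * dt)
            assert pred == pytest.approx(row["observed_cost"], rel=0.02)

    def test_negative_cost_rejected(self, panel_medium):
        cohort, panel = panel_medium
        bad = panel.copy()
        bad.loc[bad.index[0], "observed_cost"] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            fit_cost_model(bad, cohort)

    def test_empty_panel_rejected(self, panel_medium):
        cohort, panel = panel_medium
        with pytest.raises(ValueError, match="empty"):
            fit_cost_model(panel.iloc[0:0], cohort)

    def test_all_zero_component_degenerate(self, panel_medium):
        cohort, panel = panel_medium
        zeroed = panel.copy()
        zeroed["observed_cost"] = zeroed["observed_cost"] - zeroed["observed_cost_cvd"]
        zeroed["observed_cost_cvd"] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_cost_model(zeroed, cohort)


def _unit_model(**coef_overrides):
    base = {"intercept": 0.0}
    base.update(coef_overrides)
    comp = CostComponent(pd.Series(base, dtype=float),
                         np.zeros((len(base), len(base))), 1.0)
    zero = CostComponent(pd.Series({"intercept": -50.0}), np.zeros((1, 1)), 1.0)
    return CostModel(components={"cvd": comp, "other": zero})


class TestCycleCost:
    def test_zero_coefficients_give_unit_cost(self, zero_covariate_profile):
        model = _unit_model()
        got = cycle_cost_components(model, zero_covariate_profile, "stable", None, 60.0)
        assert got["cvd"] == pytest.approx(1.0)

    def test_intercept_log500_gives_500(self, zero_covariate_profile):
        model = _unit_model(intercept=np.log(500.0))
        # 'other' component is ~0, so the total is the cvd component
        assert cycle_cost(model, zero_covariate_profile, "stable", None, 60.0) == \
            pytest.approx(500.0, abs=1e-6)

    def test_acute_ratio_is_exp_gamma(self, zero_covariate_profile):
        model = _unit_model(intercept=np.log(200.0), acute=0.7, state_post_mi=0.2)
        acute = cycle_cost(model, zero_covariate_profile, "post_mi", 0, 60.0)
        later = cycle_cost(model, zero_covariate_profile, "post_mi", 10, 60.0)
        assert acute / later == pytest.approx(np.exp(0.7))

    def test_cvd_plus_other_equals_total(self, truth_cost_model, zero_covariate_profile):
        comps = cycle_cost_components(truth_cost_model, zero_covariate_profile,
                                      "post_is", 2, 70.0)
        total = cycle_cost(truth_cost_model, zero_covariate_profile, "post_is", 2, 70.0)
        assert comps["cvd"] + comps["other"] == pytest.approx(total)
        assert comps["cvd"] <= total

    def test_dead_state_rejected(self, truth_cost_model, zero_covariate_profile):
        with pytest.raises(ValueError, match="live states"):
            cycle_cost(truth_cost_model, zero_covariate_profile, "cvd_death", None, 70.0)

    def test_cost_non_negative_for_random_inputs(self, truth_cost_model):
        rng = np.random.default_rng(44)
        for _ in range(2000):
            prof = pd.Series({c: rng.random() for c in sm.COVARIATE_COLUMNS})
            prof["age_entry"] = rng.uniform(18, 110)
            state = rng.choice(["stable", "post_mi", "post_is", "post_hs"])
            cse = None if state == "stable" else int(rng.integers(0, 40))
            assert cycle_cost(truth_cost_model, prof, state, cse, prof["age_entry"]) >= 0


class TestCycleUtility:
    def _catalogue(self):
        bands = pd.DataFrame(
            [{"sex": s, "age_lo": 18, "age_hi": 110, "base_utility": 0.80}
             for s in ("male", "female")]
        )
        return UtilityCatalogue(bands, condition_multiplier=0.95,
                                event_multipliers={"post_mi": 0.90, "post_is": 0.8,
                                                   "post_hs": 0.7},
                                acute_multiplier=0.85)

    def test_multiplicative_composition(self, zero_covariate_profile):
        cat = self._catalogue()
        u = cycle_utility(cat, zero_covariate_profile, "post_mi", 5, 60.0)
        assert u == pytest.approx(0.80 * 0.95 * 0.90)

    def test_acute_decrement_only_in_event_cycle(self, zero_covariate_profile):
        cat = self._catalogue()
        u0 = cycle_utility(cat, zero_covariate_profile, "post_mi", 0, 60.0)
        u1 = cycle_utility(cat, zero_covariate_profile, "post_mi", 1, 60.0)
        assert u0 == pytest.approx(u1 * 0.85)

    def test_all_multipliers_one_returns_base(self, zero_covariate_profile):
        bands = pd.DataFrame(
            [{"sex": s, "age_lo": 18, "age_hi": 110, "base_utility": 0.77}
             for s in ("male", "female")]
        )
        cat = UtilityCatalogue(bands)
        assert cycle_utility(cat, zero_covariate_profile, "stable", None, 50.0) == \
            pytest.approx(0.77)

    def test_utility_monotone_across_age_bands(self, utilities, zero_covariate_profile):
        us = [cycle_utility(utilities, zero_covariate_profile, "stable", None, age)
              for age in (30.0, 50.0, 70.0, 90.0)]
        assert all(a >= b for a, b in zip(us, us[1:]))

    def test_all_lookups_within_eq5d_bounds(self, utilities):
        rng = np.random.default_rng(45)
        for _ in range(500):
            prof = pd.Series({c: rng.random() for c in sm.COVARIATE_COLUMNS})
            state = rng.choice(["stable", "post_mi", "post_is", "post_hs"])
            cse = None if state == "stable" else int(rng.integers(0, 10))
            u = cycle_utility(utilities, prof, state, cse, rng.uniform(18, 110))
            assert -0.594 <= u <= 1.0

    def test_missing_band_falls_back_with_warning(self, caplog):
        bands = pd.DataFrame(
            [{"sex": s, "age_lo": 40, "age_hi": 60, "base_utility": 0.8}
             for s in ("male", "female")]
        )
        cat = UtilityCatalogue(bands)
        with caplog.at_level("WARNING", logger="scadmodel.costs"):
            assert cat.base("male", 75.0) == pytest.approx(0.8)
        assert "nearest band" in caplog.text

    def test_out_of_range_multiplier_rejected(self):
        bands = pd.DataFrame(
            [{"sex": "male", "age_lo": 18, "age_hi": 110, "base_utility": 0.8}]
        )
        with pytest.raises(ValueError, match="multipliers"):
            UtilityCatalogue(bands, condition_multiplier=1.4)

    def test_beta_perturbation_stays_in_bounds(self, utilities):
        rng = np.random.default_rng(46)
        for _ in range(20):
            pert = utilities.perturbed(rng)
            assert pert.bands["base_utility"].between(-0.594, 1.0).all()
            assert 0 < pert.condition_multiplier <= 1


def test_poisson_qmle_matches_statsmodels_glm(panel_medium):
    """Independent oracle: statsmodels Poisson GLM with cluster covariance."""
    import statsmodels.api as sma

    cohort, panel = panel_medium
    sub_ids = cohort["patient_id"].iloc[:2000]
    sub = panel[panel["patient_id"].isin(sub_ids)].sort_values(
        ["patient_id", "cycle_index"]).reset_index(drop=True)
    model = fit_cost_model(sub, cohort)
    # rebuild the same design and fit with statsmodels
    from scadmodel.costs import CYCLE_LENGTH_YEARS, DEFAULT_COST_COVARIATES, LIVE_STATES
    from scadmodel.covariates import design_matrix as dm

    merged = sub.merge(cohort, on="patient_id", how="left")
    xprof = dm(merged)
    feats = pd.DataFrame({n: xprof[n].to_numpy(float) for n in DEFAULT_COST_COVARIATES})
    feats["current_age"] = (merged["age_entry"]
                            + merged["cycle_index"] * CYCLE_LENGTH_YEARS).to_numpy()
    state, cse = merged["state_at_cycle"], merged["cycles_since_event"]
    for s in LIVE_STATES[1:]:
        feats[f"state_{s}"] = (state == s).astype(float).to_numpy()
    feats["acute"] = ((state != "stable") & (cse == 0)).astype(float).to_numpy()
    feats["band_early"] = ((state != "stable") & cse.between(1, 4)).astype(float).to_numpy()
    x = sma.add_constant(feats, prepend=True).to_numpy()
    res = sma.GLM(merged["observed_cost_cvd"].to_numpy(), x,
                  family=sma.families.Poisson()).fit(
        cov_type="cluster", cov_kwds={"groups": merged["patient_id"].to_numpy()})
    ours = model.components["cvd"]
    np.testing.assert_allclose(ours.coef.to_numpy(), np.asarray(res.params),
                               rtol=1e-5, atol=1e-7)
    np.testing.assert_allclose(np.sqrt(np.diag(ours.vcov)),
                               np.asarray(res.bse), rtol=5e-3)


def test_cost_features_requires_live_state(zero_covariate_profile):
    with pytest.raises(ValueError, match="live states"):
        cost_features(zero_covariate_profile, "noncvd_death", None, 60.0)
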