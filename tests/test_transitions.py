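"""CIF composition and per-cycle transition probabilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scadmodel.transitions import (
    CYCLE_LENGTH_YEARS,
    PRIMARY_CAUSES,
    STATES,
    apply_treatment,
    build_cifs,
    post_event_transitions,
    stable_state_transitions,
)


def const(h):
    return lambda t: np.full_like(np.asarray(t, dtype=float), h)


def five_cause_hazards(h_by_cause):
    return {c: const(h_by_cause.get(c, 0.0)) for c in PRIMARY_CAUSES}


class TestBuildCifs:
    def test_exponential_closed_form(self):
        """Two constant causes: F_k(t) = (h_k/h)(1 - e^{-ht}), S = e^{-ht}."""
        cb = build_cifs({"a": const(0.10), "b": const(0.05)},
                        n_cycles=1, cycle_length=5.0, n_sub=2000)
        assert cb.cif["a"][-1] == pytest.approx((0.10 / 0.15) * (1 - np.exp(-0.75)), abs=1e-9)
        assert cb.survival[-1] == pytest.approx(np.exp(-0.75), abs=1e-9)

    def test_single_cause_complement_identity(self):
        cb = build_cifs({"only": lambda t: 0.2 + 0.05 * np.asarray(t)}, n_cycles=40)
        np.testing.assert_allclose(cb.cif["only"], 1.0 - cb.survival, atol=1e-12)

    def test_all_zero_hazards(self):
        cb = build_cifs(five_cause_hazards({}), n_cycles=20)
        assert np.all(cb.survival == 1.0)
        for f in cb.cif.values():
            assert np.all(f == 0.0)

    def test_negative_hazard_aborts(self):
        with pytest.raises(ValueError, match="negative or non-finite"):
            build_cifs({"bad": const(-0.1)}, n_cycles=5)

    def test_conservation_on_random_hazards(self):
        """S + sum(F_k) = 1 on every grid point for random hazard shapes."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            scale = rng.uniform(0.01, 0.6, size=5)
            power = rng.uniform(-0.4, 1.0, size=5)
            hz = {
                f"c{i}": (lambda t, s=scale[i], p=power[i]:
                          s * np.maximum(np.asarray(t, float), 1e-9) ** p)
                for i in range(5)
            }
            cb = build_cifs(hz, n_cycles=60)
            assert cb.conservation_error() < 1e-8

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        rates=st.lists(st.floats(0.0, 2.0, allow_nan=False), min_size=2, max_size=5),
        growth=st.floats(-0.2, 0.2, allow_nan=False),
    )
    def test_conservation_property(self, rates, growth):
        """S + sum F_k = 1 and monotonicity for arbitrary admissible hazards."""
        hz = {
            f"c{i}": (lambda t, r=r: r * np.exp(growth * np.asarray(t, float)))
            for i, r in enumerate(rates)
        }
        cb = build_cifs(hz, n_cycles=30)
        assert cb.conservation_error() < 1e-8
        assert np.all(np.diff(cb.survival) <= 1e-12)
        for f in cb.cif.values():
            assert np.all(np.diff(f) >= -1e-12)

    def test_quadrature_adequacy_halving_step(self):
        """Halving the sub-step changes no CIF value by more than 1e-7."""
        hz = {"a": lambda t: 0.1 * np.exp(0.03 * np.asarray(t)), "b": const(0.07)}
        c1 = build_cifs(hz, n_cycles=80, n_sub=16)
        c2 = build_cifs(hz, n_cycles=80, n_sub=32)
        for k in hz:
            assert np.max(np.abs(c1.cif[k] - c2.cif[k])) < 1e-7

    def test_infinite_hazard_routes_all_mass(self):
        hz = {"inf_cause": const(np.inf), "other": const(0.1)}
        cb = build_cifs(hz, n_cycles=4)
        assert cb.survival[-1] == 0.0
        assert cb.cif["inf_cause"][-1] == pytest.approx(1.0)


class TestStableTransitions:
    def test_exponential_per_cycle_formula(self):
        hz = five_cause_hazards({"mi": 0.10, "noncvd_death": 0.05})
        cb = build_cifs(hz, n_cycles=10)
        tr = stable_state_transitions(cb, 0)
        dt = CYCLE_LENGTH_YEARS
        stay = np.exp(-0.15 * dt)
        assert tr.probs[STATES.index("stable")] == pytest.approx(stay, abs=1e-10)
        assert tr.probs[STATES.index("post_mi")] == pytest.approx(
            (0.10 / 0.15) * (1 - stay), abs=1e-10)
        # later cycles identical for constant hazards
        tr5 = stable_state_transitions(cb, 5)
        np.testing.assert_allclose(tr.probs, tr5.probs, atol=1e-12)

    def test_zero_hazards_stay_probability_one(self):
        cb = build_cifs(five_cause_hazards({}), n_cycles=5)
        tr = stable_state_transitions(cb, 2)
        assert tr.probs[STATES.index("stable")] == 1.0

    def test_rows_sum_to_one_for_random_hazards(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            rates = dict(zip(PRIMARY_CAUSES, rng.uniform(0, 0.8, 5)))
            cb = build_cifs(five_cause_hazards(rates), n_cycles=3)
            tr = stable_state_transitions(cb, 1)
            assert tr.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(tr.probs >= 0)


class TestPostEventTransitions:
    def test_zero_hazards_remain_forever(self, life_table):
        from tests.conftest import constant_hazard_equations
        eqs = constant_hazard_equations(life_table, {})
        tr = post_event_transitions(
            {k: eqs.post[("mi", k)] for k in ("cvd_death", "noncvd_death")},
            sex="male", age_at_event=70.0, cycles_since_event=3,
        )
        assert tr.probs[STATES.index("post_mi")] == pytest.approx(1.0, abs=1e-10)

    def test_constant_hazard_death_split_two_to_one(self, life_table):
        from tests.conftest import constant_hazard_equations
        eqs = constant_hazard_equations(
            life_table, {}, post_rates={("mi", "cvd_death"): 0.2, ("mi", "noncvd_death"): 0.1}
        )
        tr = post_event_transitions(
            {k: eqs.post[("mi", k)] for k in ("cvd_death", "noncvd_death")},
            sex="female", age_at_event=70.0, cycles_since_event=0,
        )
        p_cvd = tr.probs[STATES.index("cvd_death")]
        p_ncvd = tr.probs[STATES.index("noncvd_death")]
        assert p_cvd / p_ncvd == pytest.approx(2.0, rel=1e-9)

    def test_death_probability_monotone_in_age(self):
        """Positive log-hazard age slope: per-cycle death risk rises with age."""
        import scadmodel as sm
        # AFT location coefficient -0.05 on age => increasing hazard with age
        coef = pd.Series({"intercept": 4.0, "sex_female": 0.0, "age_event": -0.05})
        fit = sm.SurvivalFit("cvd_death_after_mi", "exponential", coef, 1.0, None,
                             np.zeros((3, 3)), 0.0, 0, 0, "x", list(coef.index))
        zero = pd.Series({"intercept": 30.0, "sex_female": 0.0, "age_event": 0.0})
        none_fit = sm.SurvivalFit("noncvd_death_after_mi", "exponential", zero, 1.0, None,
                                  np.zeros((3, 3)), 0.0, 0, 0, "x", list(zero.index))
        prev = -1.0
        for age in (50.0, 60.0, 70.0, 80.0):
            tr = post_event_transitions(
                {"cvd_death": fit, "noncvd_death": none_fit},
                sex="male", age_at_event=age, cycles_since_event=0,
            )
            p = tr.probs[STATES.index("cvd_death")]
            assert p > prev
            prev = p


class TestApplyTreatment:
    def test_identity_at_rho_zero(self):
        hz = five_cause_hazards({"mi": 0.1, "noncvd_death": 0.05})
        out = apply_treatment(hz, 0.0)
        t = np.array([1.0, 2.0])
        for c in PRIMARY_CAUSES:
            np.testing.assert_allclose(out[c](t), hz[c](t))

    def test_scales_cvd_hazards(self):
        hz = five_cause_hazards({"mi": 0.10})
        out = apply_treatment(hz, 0.2)
        assert out["mi"](np.array([1.0]))[0] == pytest.approx(0.08)

    def test_noncvd_untouched(self):
        hz = five_cause_hazards({"noncvd_death": 0.07, "mi": 0.1})
        out = apply_treatment(hz, 0.2)
        assert out["noncvd_death"](np.array([3.0]))[0] == pytest.approx(0.07)

    def test_haemorrhagic_switch(self):
        hz = five_cause_hazards({"haemorrhagic_stroke": 0.05})
        treated = apply_treatment(hz, 0.4, treat_haemorrhagic=False)
        assert treated["haemorrhagic_stroke"](np.array([1.0]))[0] == pytest.approx(0.05)

    @pytest.mark.parametrize("rho", [-0.1, 1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(ValueError, match="rho"):
            apply_treatment(five_cause_hazards({}), rho)

    def test_treatment_monotonicity_of_cifs(self):
        """CVD CIFs non-increasing, non-CVD CIF non-decreasing in rho."""
        hz = five_cause_hazards(
            {"mi": 0.08, "ischaemic_stroke": 0.05, "haemorrhagic_stroke": 0.01,
             "cvd_death": 0.06, "noncvd_death": 0.09})
        prev = None
        for rho in (0.0, 0.1, 0.2, 0.3, 0.4):
            cb = build_cifs(apply_treatment(hz, rho), n_cycles=100)
            if prev is not None:
                for c in ("mi", "ischaemic_stroke", "haemorrhagic_stroke", "cvd_death"):
                    assert np.all(cb.cif[c] <= prev.cif[c] + 1e-12)
                assert np.all(cb.cif["noncvd_death"] >= prev.cif["noncvd_death"] - 1e-12)
            prev = cb
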