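"""Structural-model tests: closed forms against ODE and superposition oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ode_concentration
from siropk.model import PopulationModel
from siropk.pk import (
    DoseEvent,
    PKParameters,
    Regimen,
    concentration_after_single_dose,
    concentration_profile,
    individual_params,
    steady_state_trough,
)


class TestIndividualParams:
    def test_typical_values_at_standard_weight(self, final_model):
        p = individual_params(final_model, 70.0)
        assert p.cl_over_f == pytest.approx(6.48)
        assert p.v_over_f == pytest.approx(124.0)
        assert p.ka == pytest.approx(0.485)

    def test_per_kg_clearance_at_5kg(self, final_model):
        p = individual_params(final_model, 5.0)
        assert round(p.cl_over_f / 5.0, 2) == 0.18

    def test_eta_scales_lognormally(self, final_model):
        p = individual_params(final_model, 70.0, eta_cl=np.log(2.0))
        assert p.cl_over_f == pytest.approx(12.96)

    @pytest.mark.parametrize("weight", [0.0, -3.0, np.nan])
    def test_invalid_weight_rejected(self, final_model, weight):
        with pytest.raises(ValueError):
            individual_params(final_model, weight)

    def test_per_kg_clearance_strictly_decreasing_5_to_60(self, final_model):
        weights = np.linspace(5.0, 60.0, 56)
        per_kg = [individual_params(final_model, w).cl_over_f / w for w in weights]
        assert np.all(np.diff(per_kg) < 0)


class TestSingleDose:
    def test_zero_at_time_zero_and_zero_dose(self):
        p = PKParameters(6.48, 124.0, 0.485)
        assert concentration_after_single_dose(p, 1.0, 0.0) == 0.0
        assert concentration_after_single_dose(p, 0.0, 12.0) == 0.0

    def test_matches_ode_oracle_frozen_example(self):
        # 1 mg oral, published typical 70-kg parameters, 24 h post dose
        p = PKParameters(6.48, 124.0, 0.485)
        assert concentration_after_single_dose(p, 1.0, 24.0) == pytest.approx(
            2.5786, abs=1e-3
        )

    @pytest.mark.parametrize(
        "cl,v,ka",
        [(6.48, 124.0, 0.485), (0.9, 8.9, 0.485), (2.0, 30.0, 1.5), (5.0, 20.0, 0.05)],
    )
    def test_matches_ode_oracle_grid(self, cl, v, ka):
        p = PKParameters(cl, v, ka)
        times = np.array([0.5, 2.0, 8.0, 24.0, 48.0])
        closed = concentration_after_single_dose(p, 2.5, times)
        numeric = ode_concentration(cl, v, ka, 2.5, times)
        assert np.allclose(closed, numeric, rtol=1e-6)

    def test_ka_equals_ke_limit_continuous(self):
        # the switch to the coincident-rate branch must be seamless
        v, ka = 50.0, 0.3
        p_exact = PKParameters(ka * v, v, ka)
        p_near = PKParameters(ka * v * (1 + 1e-7), v, ka)
        t = np.array([1.0, 5.0, 20.0])
        a = concentration_after_single_dose(p_exact, 1.0, t)
        b = concentration_after_single_dose(p_near, 1.0, t)
        assert np.allclose(a, b, rtol=1e-5)
        assert np.allclose(a, ode_concentration(ka * v, v, ka, 1.0, t), rtol=1e-6)

    def test_negative_time_rejected(self):
        p = PKParameters(6.48, 124.0, 0.485)
        with pytest.raises(ValueError):
            concentration_after_single_dose(p, 1.0, -1.0)


class TestProfile:
    def test_single_dose_history_degenerates(self):
        p = PKParameters(2.0, 30.0, 0.485)
        prof = concentration_profile(p, [DoseEvent(0.0, 1.5)], [6.0, 12.0])
        single = concentration_after_single_dose(p, 1.5, np.array([6.0, 12.0]))
        assert np.allclose(prof, single)

    def test_time_before_first_dose_is_zero(self):
        p = PKParameters(2.0, 30.0, 0.485)
        prof = concentration_profile(p, [DoseEvent(10.0, 1.0)], [5.0, 15.0])
        assert prof[0] == 0.0 and prof[1] > 0.0

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_dose_linearity(self, scale):
        p = PKParameters(2.0, 30.0, 0.485)
        doses = [DoseEvent(24.0 * k, 0.5) for k in range(5)]
        scaled = [DoseEvent(d.time, d.amount * scale) for d in doses]
        t = np.array([10.0, 50.0, 120.0])
        assert np.allclose(
            concentration_profile(p, scaled, t),
            scale * concentration_profile(p, doses, t),
            rtol=1e-12,
        )

    @given(
        cl=st.floats(0.5, 10.0),
        v=st.floats(5.0, 200.0),
        t=st.floats(0.0, 500.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_non_negativity(self, cl, v, t):
        p = PKParameters(cl, v, 0.485)
        doses = [DoseEvent(12.0 * k, 1.0) for k in range(10)]
        assert concentration_profile(p, doses, [t])[0] >= 0.0


class TestSteadyState:
    def test_zero_dose(self):
        p = PKParameters(2.0, 30.0, 0.485)
        assert steady_state_trough(p, 0.0, 24.0) == 0.0

    def test_invalid_tau(self):
        p = PKParameters(2.0, 30.0, 0.485)
        with pytest.raises(ValueError):
            steady_state_trough(p, 1.0, 0.0)

    @pytest.mark.parametrize(
        "weight,amount,expected",
        [(5.0, 0.5, 6.9139), (10.0, 1.0, 10.2293)],
    )
    def test_typical_trough_frozen_superposition_values(
        self, final_model, weight, amount, expected
    ):
        p = individual_params(final_model, weight)
        assert steady_state_trough(p, amount, 24.0) == pytest.approx(expected, abs=2e-4)

    @pytest.mark.parametrize("weight", [5.0, 22.0, 60.0])
    def test_agrees_with_long_superposition(self, final_model, weight):
        p = individual_params(final_model, weight)
        tau = 24.0
        # 20 half-lives of repeated dosing
        n = max(int(np.ceil(20 * p.half_life / tau)) + 1, 120)
        doses = [DoseEvent(tau * k, 0.5) for k in range(n)]
        trough_sup = concentration_profile(p, doses, [n * tau])[0]
        assert abs(steady_state_trough(p, 0.5, tau) - trough_sup) < 1e-6

    def test_ka_equals_ke_accumulation_limit(self):
        v, ka, tau = 40.0, 0.2, 24.0
        exact = PKParameters(ka * v, v, ka)
        near = PKParameters(ka * v * (1 + 1e-7), v, ka)
        assert steady_state_trough(exact, 1.0, tau) == pytest.approx(
            steady_state_trough(near, 1.0, tau), rel=1e-5
        )


class TestRegimen:
    def test_bid_splits_daily_dose_evenly(self):
        qd = Regimen(0.06, "qd")
        bid = Regimen(0.06, "bid")
        assert qd.tau == 24.0 and bid.tau == 12.0
        assert qd.amount_per_dose(20.0) == pytest.approx(1.2)
        assert bid.amount_per_dose(20.0) == pytest.approx(0.6)
        assert 2 * bid.amount_per_dose(20.0) == qd.amount_per_dose(20.0)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError):
            Regimen(0.05, "tid")
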