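"""Treatment model: thresholds, regimes, resistance, failure detection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

import adtsim as ad
from adtsim.tumor import FullModelParams, ResistanceParams, g2, simulate_asymptotic_psa, threshold_by_bisection


@pytest.fixture
def base_params(strong_cascade_hormones):
    law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
    return FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones)


class TestCriticalRate:
    def test_direct_product(self, base_params):
        p = base_params
        assert ad.critical_growth_rate(p) == pytest.approx(p.dP * p.z0_bar)

    def test_castrate_resistant_limit(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        p = FullModelParams(growth=law, dP=0.0, hormones=strong_cascade_hormones)
        assert ad.critical_growth_rate(p) == 0.0
        # a > a_tilde always: no cure at any dose
        rep = ad.classify_regime(p, L=100.0)
        assert rep.regime == "no_positive_SS_unbounded"

    def test_composes_with_steady_state_quadratic(self, base_params):
        assert ad.critical_growth_rate(base_params) == pytest.approx(
            base_params.dP * (-1.0 + math.sqrt(21.0)), rel=1e-12
        )


class TestThreshold:
    def test_threshold_at_detection_when_deficit_marginal(self, strong_cascade_hormones):
        # tune a so that dP (z0 - z_L) = a exactly: P_bar collapses to P_R
        h = strong_cascade_hormones
        L = 2.0
        z0 = ad.steady_state_two_with_drug(h, 0.0)[1]
        zL = ad.steady_state_two_with_drug(h, L)[1]
        dP = 2e-3
        a = dP * (z0 - zL) * (1.0 - 1e-12)
        law = ad.GrowthLawSpec("log_power", {"a": a, "b": 1.0, "gamma": 0.5})
        p = FullModelParams(growth=law, dP=dP, hormones=h)
        assert ad.psa_threshold(p, L) == pytest.approx(law.p_r, rel=1e-6)

    def test_no_threshold_above_critical_rate(self, strong_cascade_hormones):
        h = strong_cascade_hormones
        dP = 2e-3
        a_tilde = dP * ad.steady_state_two_with_drug(h, 0.0)[1]
        law = ad.GrowthLawSpec("log_power", {"a": 1.05 * a_tilde, "b": 1.0, "gamma": 0.5})
        p = FullModelParams(growth=law, dP=dP, hormones=h)
        for L in [0.0, 1.0, 100.0, 1e5]:
            assert ad.psa_threshold(p, L) is None

    def test_threshold_increasing_in_dose(self, base_params):
        L_grid = np.linspace(1.0, 30.0, 15)
        vals = [ad.psa_threshold(base_params, L) for L in L_grid]
        assert all(v is not None and v >= base_params.growth.p_r for v in vals)
        assert np.all(np.diff(vals) > 0)

    def test_non_log_power_law_rejected(self, strong_cascade_hormones):
        p = FullModelParams(
            growth=ad.GrowthLawSpec("exponential", {"a": 1e-3}),
            dP=2e-3, hormones=strong_cascade_hormones,
        )
        with pytest.raises(ValueError):
            ad.psa_threshold(p, 1.0)

    def test_bisection_oracle_matches_formula(self, base_params):
        L = 2.0
        P_bar = ad.psa_threshold(base_params, L)
        P_bis = threshold_by_bisection(base_params, L)
        assert abs(P_bis - P_bar) / P_bar < 0.01

    def test_fate_flips_at_threshold(self, base_params):
        L = 2.0
        P_bar = ad.psa_threshold(base_params, L)
        assert simulate_asymptotic_psa(base_params, L, 0.9 * P_bar, horizon=1e5) == "decay"
        assert simulate_asymptotic_psa(base_params, L, 1.1 * P_bar, horizon=1e5) == "escape"


class TestRegimeClassification:
    def test_supercritical_growth_escapes(self, strong_cascade_hormones):
        h = strong_cascade_hormones
        dP = 2e-3
        a_tilde = dP * ad.steady_state_two_with_drug(h, 0.0)[1]
        law = ad.GrowthLawSpec("log_power", {"a": 1.2 * a_tilde, "b": 1.0, "gamma": 0.5})
        p = FullModelParams(growth=law, dP=dP, hormones=h)
        rep = ad.classify_regime(p, L=50.0, P0=2.0)
        assert rep.regime == "no_positive_SS_unbounded"
        assert rep.P_bar is None
        assert rep.predicted_fate == "escape"
        assert simulate_asymptotic_psa(p, 50.0, 2.0, horizon=2e5) == "escape"

    def test_threshold_regime_and_non_generic_start(self, base_params):
        rep = ad.classify_regime(base_params, L=2.0, P0=None)
        assert rep.regime == "threshold_exists"
        rep2 = ad.classify_regime(base_params, L=2.0, P0=rep.P_bar)
        assert rep2.predicted_fate == "non_generic"

    def test_dose_too_small_regime(self, strong_cascade_hormones):
        h = strong_cascade_hormones
        dP = 2e-3
        z0 = ad.steady_state_two_with_drug(h, 0.0)[1]
        zL = ad.steady_state_two_with_drug(h, 0.05)[1]
        a = 1.5 * dP * (z0 - zL)  # below a_tilde but above the deficit at this L
        assert a < dP * z0
        law = ad.GrowthLawSpec("log_power", {"a": a, "b": 1.0, "gamma": 0.5})
        p = FullModelParams(growth=law, dP=dP, hormones=h)
        rep = ad.classify_regime(p, L=0.05, P0=3.0)
        assert rep.regime == "no_positive_SS_unbounded"
        assert "dose too small" in rep.effective_condition


class TestResistance:
    def test_closed_form_against_scalar_ode(self):
        beta, l, L = 2e-3, 0.8, 2.5
        sol = solve_ivp(
            lambda t, r: [beta * L * (1.0 - r[0] / l)],
            (0.0, 3000.0), [0.0], t_eval=np.linspace(0.0, 3000.0, 50),
            rtol=1e-12, atol=1e-14,
        )
        closed = ad.resistance_closed_form(sol.t, beta, l, L)
        assert np.max(np.abs(sol.y[0] - closed)) < 1e-8

    def test_half_saturation_time(self):
        beta, l, L = 1e-3, 0.6, 3.0
        t_half = (l / (beta * L)) * math.log(2.0)
        assert ad.resistance_closed_form(t_half, beta, l, L) == pytest.approx(l / 2)

    def test_initial_and_asymptotic_levels(self):
        assert ad.resistance_closed_form(0.0, 1e-3, 0.6, 3.0) == 0.0
        assert ad.resistance_closed_form(1e9, 1e-3, 0.6, 3.0) == pytest.approx(0.6)

    def test_g2_band_and_endpoints(self):
        L, a2, l2 = 4.0, 1.5, 1.2
        assert g2(0.0, L, a2) == pytest.approx(L)
        r = np.linspace(0.0, l2, 50)
        vals = g2(r, L, a2)
        assert np.all(np.diff(vals) < 0)
        lower = L * (a2 + math.exp(l2)) / ((a2 + 1.0) * math.exp(l2))
        assert np.all(vals >= lower - 1e-12)
        assert np.all(vals <= L + 1e-12)
        # limit for r -> infinity is L/(a2+1)
        assert g2(50.0, L, a2) == pytest.approx(L / (a2 + 1.0), rel=1e-6)


class TestFullModel:
    def test_resistance_off_reduces_to_treated_model(self, base_params):
        t = np.linspace(0.0, 2000.0, 100)
        df = ad.integrate_full_model(base_params, 2.0, 5.0, t)
        assert np.all(df["r1"] == 0.0)
        assert np.all(df["r2"] == 0.0)
        # hormones converge to the drugged steady state
        x_star, z_star = ad.steady_state_two_with_drug(base_params.hormones, 2.0)
        assert df["x"].iloc[-1] == pytest.approx(x_star, rel=1e-6)
        assert df["z"].iloc[-1] == pytest.approx(z_star, rel=1e-6)

    def test_untreated_hormones_return_to_baseline(self, base_params):
        t = np.linspace(0.0, 2000.0, 60)
        df = ad.integrate_full_model(base_params, 0.0, 5.0, t, x0=0.5, z0=0.5)
        assert df["x"].iloc[-1] == pytest.approx(base_params.x0_bar, rel=1e-6)
        assert df["z"].iloc[-1] == pytest.approx(base_params.z0_bar, rel=1e-6)
        # with z at baseline, PSA follows the pure growth law asymptotically
        y_end = math.log(df["P"].iloc[-1] / base_params.growth.p_r)
        y_mid = math.log(df["P"].iloc[30] / base_params.growth.p_r)
        assert y_end > y_mid  # growing without treatment

    def test_resistance_bounded_by_saturation_levels(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta1=3e-3, beta2=4e-3, l1=0.7, l2=1.3, a1=1.0, a2=1.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        t = np.linspace(0.0, 8000.0, 200)
        df = ad.integrate_full_model(p, 2.0, 5.0, t)
        # r_i never exceeds l_i (saturation approached, never crossed,
        # up to the integrator's absolute tolerance)
        assert np.all(df["r1"] <= r.l1 + 1e-8)
        assert np.all(df["r2"] <= r.l2 + 1e-8)
        closed1 = ad.resistance_closed_form(df["time"].to_numpy(), r.beta1, r.l1, 2.0)
        assert np.max(np.abs(df["r1"].to_numpy() - closed1)) < 1e-7

    def test_time_varying_drug_accepted(self, base_params):
        t = np.linspace(0.0, 500.0, 40)
        df = ad.integrate_full_model(base_params, lambda ti: 2.0 + math.sin(ti / 50.0), 5.0, t)
        assert np.all(df["L"] > 0)

    def test_blow_up_reported_in_attrs(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 0.05, "b": 3.0, "gamma": 0.9})
        p = FullModelParams(growth=law, dP=1e-4, hormones=strong_cascade_hormones)
        t = np.linspace(0.0, 3e4, 300)
        df = ad.integrate_full_model(p, 0.0, 100.0, t, psa_cap=1e6)
        assert "blow_up" in df.attrs
        lo, hi = df.attrs["blow_up"]
        assert lo < hi


class TestReducedResistanceSystem:
    def test_converges_to_proposition_steady_state(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta2=3e-3, l2=1.2, a2=1.5)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        L = 2.0
        t = np.linspace(0.0, 3e4, 100)
        df = ad.reduced_resistance_system(p, L, t)
        x_star, z_star, r2_star = ad.reduced_resistance_steady_state(p, L)
        assert abs(df["r2"].iloc[-1] - r.l2) < 1e-6
        assert df["z"].iloc[-1] == pytest.approx(z_star, rel=1e-8)
        assert df["x"].iloc[-1] == pytest.approx(x_star, rel=1e-8)

    def test_multi_start_convergence_small_dose(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta2=3e-3, l2=1.0, a2=1.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        L = 0.3
        x_star, z_star, _ = ad.reduced_resistance_steady_state(p, L)
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 5e4, 50)
        for _ in range(10):
            x0, z0 = rng.uniform(0.05, 8.0, size=2)
            df = ad.reduced_resistance_system(p, L, t, x0=x0, z0=z0)
            assert df["z"].iloc[-1] == pytest.approx(z_star, rel=1e-6)

    def test_saturated_resistance_raises_testosterone(self, strong_cascade_hormones):
        # larger a2 and l2 weaken the effective drug, raising asymptotic TES
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        L = 2.0
        z_no_res = ad.steady_state_two_with_drug(strong_cascade_hormones, L)[1]
        r = ResistanceParams(beta2=3e-3, l2=2.0, a2=5.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        _, z_res, _ = ad.reduced_resistance_steady_state(p, L)
        z0 = ad.steady_state_two_with_drug(strong_cascade_hormones, 0.0)[1]
        assert z_no_res < z_res < z0


class TestCase1AdjustedThreshold:
    def test_saturated_mechanism_one_shrinks_threshold(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta1=1e-3, l1=0.5, a1=1.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        L = 4.0
        plain = ad.psa_threshold(p, L)
        adjusted = ad.psa_threshold(p, L, saturated_r1=True)
        assert adjusted is not None and adjusted < plain

    def test_adjusted_threshold_matches_fate_bisection(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta1=1e-3, l1=0.5, a1=1.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        L = 4.0
        P_bar = ad.psa_threshold(p, L, saturated_r1=True)
        P_bis = threshold_by_bisection(p, L, saturated_r1=True)
        assert abs(P_bis - P_bar) / P_bar < 0.01

    def test_alternative_typographic_reading_available(self, strong_cascade_hormones):
        law = ad.GrowthLawSpec("log_power", {"a": 1e-3, "b": 1.0, "gamma": 0.5})
        r = ResistanceParams(beta1=1e-3, l1=0.5, a1=1.0)
        p = FullModelParams(growth=law, dP=2e-3, hormones=strong_cascade_hormones,
                            resistance=r)
        v1 = ad.psa_threshold(p, 4.0, saturated_r1=True, extra_dp_factor=False)
        v2 = ad.psa_threshold(p, 4.0, saturated_r1=True, extra_dp_factor=True)
        assert v1 != v2


class TestBiochemicalFailure:
    def test_monotone_decline_never_fails(self):
        t = np.linspace(0.0, 100.0, 50)
        psa = 10.0 * np.exp(-0.05 * t)
        assert ad.detect_biochemical_failure(t, psa) is None

    def test_v_shape_crossing_detected_at_constructed_time(self):
        # nadir 2 at t = 50, linear rise crossing 2x nadir (= 4) at t = 70
        t = np.array([0.0, 25.0, 50.0, 60.0, 70.0, 80.0])
        psa = np.array([10.0, 6.0, 2.0, 3.0, 4.0, 5.0])
        t_fail = ad.detect_biochemical_failure(t, psa, rise_factor=2.0)
        assert t_fail == pytest.approx(70.0, abs=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            ad.detect_biochemical_failure(np.array([]), np.array([]))

    def test_dataframe_input(self):
        df = pd.DataFrame({"time": [0.0, 10.0, 20.0], "P": [4.0, 1.0, 3.0]})
        assert ad.detect_biochemical_failure(df) is not None
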