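"""Formaldehyde mass-action dynamics against the closed-form oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdhflux.dynamics import (
    KineticState,
    SimulationConfig,
    Timecourse,
    analytic_solution,
    analytic_steady_state,
    detect_steady_state,
    enzyme_dose_scan,
    formaldehyde_rate,
    simulate,
)

positive = st.floats(min_value=0.05, max_value=20.0)


class TestRateAndSteadyState:
    def test_rate_at_zero_formaldehyde_is_pure_production(self):
        state = KineticState(k1=2.0, k_minus1=1.0, k2=0.5, nad=0.5, methanol=3.0)
        assert formaldehyde_rate(0.0, state) == pytest.approx(2.0 * 0.5 * 3.0)

    def test_rate_balances_at_unit_point(self):
        state = KineticState(k1=1.0, k_minus1=0.5, k2=0.5)
        assert formaldehyde_rate(1.0, state) == pytest.approx(0.0)

    def test_rate_vanishes_at_analytic_steady_state(self):
        state = KineticState(k1=1.3, k_minus1=0.4, k2=0.9, nadh=2.0, ru5p=0.3)
        assert formaldehyde_rate(analytic_steady_state(state), state) == pytest.approx(
            0.0, abs=1e-14)

    def test_no_sink_reduces_to_equilibrium_concentration(self):
        state = KineticState(k1=2.0, k_minus1=0.5, k2=0.0)
        assert analytic_steady_state(state) == pytest.approx(2.0 / 0.5)

    def test_sink_pulls_below_equilibrium_by_one_plus_beta(self):
        # with sink flux beta times the reverse flux: F_ss = F_eq/(1+beta)
        beta = 0.2529
        eq_state = KineticState(k1=1.0, k_minus1=1.0, k2=0.0)
        state = KineticState(k1=1.0, k_minus1=1.0, k2=beta)
        assert analytic_steady_state(state) == pytest.approx(
            analytic_steady_state(eq_state) / (1 + beta))

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(k1=positive, k_minus1=positive, k2=positive, c=positive)
    def test_joint_scaling_invariance(self, k1, k_minus1, k2, c):
        a = KineticState(k1=k1, k_minus1=k_minus1, k2=k2)
        b = KineticState(k1=c * k1, k_minus1=c * k_minus1, k2=c * k2)
        assert analytic_steady_state(a) == pytest.approx(analytic_steady_state(b), rel=1e-12)

    def test_unbounded_accumulation_rejected(self):
        with pytest.raises(ValueError):
            analytic_steady_state(KineticState(k1=1.0, k_minus1=0.0, k2=0.0))


class TestAnalyticSolution:
    def test_initial_and_asymptotic_values(self):
        state = KineticState(k1=1.0, k_minus1=0.5, k2=0.5)
        assert analytic_solution(state, 0.0, f0=0.3) == pytest.approx(0.3)
        assert analytic_solution(state, 1e6) == pytest.approx(analytic_steady_state(state))

    def test_half_life_identity(self):
        state = KineticState(k1=1.0, k_minus1=0.7, k2=0.3)
        t_half = np.log(2) / state.relaxation_rate
        assert analytic_solution(state, t_half) == pytest.approx(
            analytic_steady_state(state) / 2)


class TestSimulate:
    def test_zero_production_stays_zero(self):
        state = KineticState(k1=0.0, k_minus1=1.0, k2=1.0)
        tc = simulate(state, SimulationConfig(t_end=5.0))
        assert np.all(tc.formaldehyde == 0.0)

    def test_adaptive_matches_oracle_on_random_sweep(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            k1, k_minus1, k2, f0 = rng.uniform(0.1, 5.0, size=4)
            state = KineticState(k1=k1, k_minus1=k_minus1, k2=k2)
            lam = state.relaxation_rate
            config = SimulationConfig(t_end=10.0 / lam, f0=f0, method="adaptive")
            tc = simulate(state, config)
            exact = analytic_solution(state, tc.times, f0=f0)
            fss = analytic_steady_state(state)
            assert np.max(np.abs(tc.formaldehyde - exact)) < 1e-6 * fss

    def test_euler_truncation_error_at_reference_step(self):
        state = KineticState(k1=1.0, k_minus1=0.6, k2=0.4)
        lam = state.relaxation_rate
        tc = simulate(state, SimulationConfig(dt=0.002, t_end=5.0 / lam, method="euler"))
        exact = analytic_solution(state, tc.times[-1])
        assert abs(tc.formaldehyde[-1] - exact) / exact < 0.005

    def test_euler_terminal_value_reaches_steady_state(self):
        state = KineticState(k1=2.0, k_minus1=1.0, k2=1.0)
        lam = state.relaxation_rate
        tc = simulate(state, SimulationConfig(dt=0.002, t_end=10.0 / lam, method="euler"))
        assert tc.formaldehyde[-1] == pytest.approx(analytic_steady_state(state), rel=0.01)

    def test_euler_instability_guard(self):
        state = KineticState(k1=1.0, k_minus1=500.0, k2=500.0)
        with pytest.raises(ValueError, match="dt"):
            simulate(state, SimulationConfig(dt=0.002, t_end=1.0, method="euler"))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(k1=positive, k_minus1=positive, k2=positive,
           f0=st.floats(min_value=0.0, max_value=10.0))
    def test_adaptive_non_negative(self, k1, k_minus1, k2, f0):
        state = KineticState(k1=k1, k_minus1=k_minus1, k2=k2)
        config = SimulationConfig(t_end=10.0 / state.relaxation_rate, f0=f0)
        tc = simulate(state, config)
        assert np.all(tc.formaldehyde >= 0.0)

    def test_metadata_snapshot(self):
        state = KineticState(k1=1.0, k_minus1=1.0, k2=1.0)
        tc = simulate(state, SimulationConfig(t_end=2.0))
        assert tc.metadata["k1"] == 1.0 and tc.metadata["time_units"] == "arbitrary"


class TestDoseScan:
    def test_unit_factor_is_identity(self):
        state = KineticState(k1=1.0, k_minus1=1.0, k2=0.5)
        result = enzyme_dose_scan(state, 1.0)
        assert result.gain == pytest.approx(1.0)

    def test_near_equilibrium_regime_insensitive(self):
        # reverse flux dominates the sink 100:1 -> 4x enzyme barely helps
        state = KineticState(k1=1.0, k_minus1=100.0, k2=1.0)
        result = enzyme_dose_scan(state, 4.0)
        assert result.gain == pytest.approx(4 * 101 / 401, rel=1e-12)
        assert result.gain < 1.05

    def test_far_from_equilibrium_regime_proportional(self):
        state = KineticState(k1=1.0, k_minus1=1.0, k2=100.0)
        result = enzyme_dose_scan(state, 4.0)
        assert result.gain == pytest.approx(4 * 101 / 104, rel=1e-12)
        assert result.gain > 3.8

    def test_closed_form_gain_across_regimes(self):
        for k_minus1, k2 in [(10.0, 1.0), (1.0, 1.0), (1.0, 10.0)]:
            state = KineticState(k1=1.0, k_minus1=k_minus1, k2=k2)
            c = 4.0
            expected = c * (k_minus1 + k2) / (c * k_minus1 + k2)
            assert enzyme_dose_scan(state, c).gain == pytest.approx(expected, rel=1e-12)

    def test_k1_only_mode_scales_steady_state_everywhere(self):
        state = KineticState(k1=1.0, k_minus1=100.0, k2=1.0)
        result = enzyme_dose_scan(state, 4.0, mode="k1_only")
        assert result.gain == pytest.approx(4.0)


class TestDetectSteadyState:
    def test_constant_trace(self):
        tc = Timecourse(np.linspace(0, 10, 20), np.full(20, 3.3))
        det = detect_steady_state(tc)
        assert det.reached and det.value == pytest.approx(3.3)

    def test_truncated_rise_not_reached(self):
        state = KineticState(k1=1.0, k_minus1=0.5, k2=0.5)
        lam = state.relaxation_rate
        t = np.linspace(0, 1.0 / lam, 50)
        tc = Timecourse(t, analytic_solution(state, t))
        assert not detect_steady_state(tc).reached

    def test_full_relaxation_recovers_plateau(self):
        state = KineticState(k1=1.0, k_minus1=0.5, k2=0.5)
        lam = state.relaxation_rate
        t = np.linspace(0, 10.0 / lam, 200)
        tc = Timecourse(t, analytic_solution(state, t))
        det = detect_steady_state(tc)
        assert det.reached
        assert det.value == pytest.approx(analytic_steady_state(state), rel=1e-3)

    def test_needs_enough_points(self):
        tc = Timecourse(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError):
            detect_steady_state(tc, window=5)
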