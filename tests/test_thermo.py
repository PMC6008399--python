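"""Gibbs-energy arithmetic and the paired-steady-state reversibility bound."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdhflux import thermo
from mdhflux.thermo import (
    ConcentrationState,
    R_GAS,
    SteadyStateObservation,
    delta_g,
    dg_from_flux_ratio,
    equilibrium_concentration,
    flux_ratio_from_dg,
    forward_fraction_from_flux_ratio,
    propagate_uncertainty,
    reaction_quotient,
    reversibility_bound,
    reversibility_bound_from_ratio,
)

T37 = 310.15


class TestReactionQuotient:
    @pytest.mark.parametrize(
        "state,expected",
        [
            (ConcentrationState(methanol=1, formaldehyde=1, nad=1, nadh=1), 1.0),
            (ConcentrationState(methanol=0.25, formaldehyde=5.0e-5, nad_ratio=31.3),
             5.0e-5 / (0.25 * 31.3)),
            (ConcentrationState(methanol=1, formaldehyde=0, nad=1, nadh=1), 0.0),
        ],
    )
    def test_examples(self, state, expected):
        assert reaction_quotient(state) == pytest.approx(expected, rel=1e-12)

    def test_ratio_mode_equals_absolute_mode(self):
        absolute = ConcentrationState(methanol=0.25, formaldehyde=5e-5, nad=3.13, nadh=0.1)
        ratio = ConcentrationState(methanol=0.25, formaldehyde=5e-5, nad_ratio=31.3)
        assert reaction_quotient(absolute) == pytest.approx(reaction_quotient(ratio))

    def test_zero_methanol_names_the_field(self):
        state = ConcentrationState(methanol=0, formaldehyde=1e-5, nad_ratio=31.3)
        with pytest.raises(ZeroDivisionError, match="methanol"):
            reaction_quotient(state)

    def test_requires_some_nad_information(self):
        with pytest.raises(ValueError):
            ConcentrationState(methanol=1, formaldehyde=1)


class TestDeltaG:
    def test_ln1_is_zero(self):
        assert delta_g(34.2, 1.0, 298.15) == 34.2

    def test_equilibrium_by_construction(self):
        q = math.exp(-34.2 / (R_GAS * T37))
        assert delta_g(34.2, q, T37) == pytest.approx(0.0, abs=1e-12)

    def test_uphill_reaction_near_equilibrium_in_vivo(self):
        # printed in-vivo-like quotient leaves only ~+3.4 kJ/mol of the +34.2 barrier
        q = 5.0e-5 / (0.25 * 31.3)
        assert delta_g(34.2, q, T37) == pytest.approx(
            34.2 + R_GAS * T37 * math.log(q), rel=1e-12)
        assert delta_g(34.2, q, T37) == pytest.approx(3.4, abs=0.1)

    def test_zero_quotient_sentinel(self):
        with pytest.warns(UserWarning):
            assert delta_g(34.2, 0.0) == -math.inf

    def test_negative_quotient_rejected(self):
        with pytest.raises(ValueError):
            delta_g(34.2, -1.0)


class TestEquilibriumConcentration:
    def test_identity_case(self):
        state = ConcentrationState(methanol=1, formaldehyde=0, nad=1, nadh=1)
        assert equilibrium_concentration(0.0, state) == pytest.approx(1.0)

    def test_printed_conditions(self):
        # 250 mM methanol, NAD:NADH = 31.3, 37 C: equilibrium formaldehyde
        # lands in the tens-of-uM range that makes the pathway marginal
        state = ConcentrationState(methanol=0.25, formaldehyde=0, nad_ratio=31.3)
        ceq = equilibrium_concentration(34.2, state)
        # frozen from exp(-34.2/(R*310.15)) * 0.25 * 31.3
        assert ceq == pytest.approx(1.3607e-5, rel=1e-4)

    def test_linearity_in_methanol(self):
        s1 = ConcentrationState(methanol=0.25, formaldehyde=0, nad_ratio=31.3)
        s2 = ConcentrationState(methanol=0.50, formaldehyde=0, nad_ratio=31.3)
        assert equilibrium_concentration(34.2, s2) == pytest.approx(
            2 * equilibrium_concentration(34.2, s1))

    def test_solution_zeroes_delta_g(self):
        state = ConcentrationState(methanol=0.25, formaldehyde=0, nad_ratio=31.3)
        ceq = equilibrium_concentration(34.2, state)
        at_eq = ConcentrationState(methanol=0.25, formaldehyde=ceq, nad_ratio=31.3)
        assert delta_g(34.2, reaction_quotient(at_eq), T37) == pytest.approx(0.0, abs=1e-9)

    def test_cannot_solve_dinucleotide_in_ratio_mode(self):
        state = ConcentrationState(methanol=0.25, formaldehyde=1e-5, nad_ratio=31.3)
        with pytest.raises(ValueError):
            equilibrium_concentration(34.2, state, solve_for="nadh")


class TestFluxForce:
    @pytest.mark.parametrize(
        "dg,expected",
        [(0.0, 1.0), (-R_GAS * T37 * math.log(3.0), 3.0)],
    )
    def test_examples(self, dg, expected):
        assert flux_ratio_from_dg(dg, T37) == pytest.approx(expected, rel=1e-12)

    def test_small_positive_dg_mostly_reverse(self):
        assert flux_ratio_from_dg(3.4, T37) == pytest.approx(0.268, abs=0.002)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(dg=st.floats(min_value=-50, max_value=50))
    def test_roundtrip_identity(self, dg):
        assert dg_from_flux_ratio(flux_ratio_from_dg(dg, T37), T37) == pytest.approx(
            dg, abs=1e-10)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(r=st.floats(min_value=1e-6, max_value=1e6))
    def test_forward_fraction_complementarity(self, r):
        assert forward_fraction_from_flux_ratio(r) + forward_fraction_from_flux_ratio(
            1.0 / r) == pytest.approx(1.0, abs=1e-12)


class TestReversibilityBound:
    @pytest.mark.parametrize(
        "ratio,expected_fraction,expected_percent",
        [
            (1.2, 1.2 / 2.2, 55),   # unsupplemented
            (3.0, 0.75, 75),        # glycolysis inhibition + FBPase overexpression
            (4.7, 4.7 / 5.7, 82),   # xylose-supplemented
            (1.0, 0.50, 50),        # equilibrium limit
        ],
    )
    def test_printed_fold_reductions(self, ratio, expected_fraction, expected_percent):
        est = reversibility_bound_from_ratio(ratio)
        assert est.bound_kind == "lower_bound"
        assert est.forward_fraction == pytest.approx(expected_fraction, rel=1e-12)
        assert est.percent == expected_percent

    def test_monotone_in_fold_ratio(self):
        fractions = [reversibility_bound_from_ratio(r).forward_fraction
                     for r in np.linspace(1.0, 10.0, 50)]
        assert np.all(np.diff(fractions) >= 0)

    def test_paired_observations_with_matched_nad(self):
        obs1 = SteadyStateObservation(formaldehyde_um=52, formaldehyde_sd_um=1,
                                      pathway="mdh_only")
        obs2 = SteadyStateObservation(formaldehyde_um=17, formaldehyde_sd_um=1.5,
                                      pathway="full_pathway")
        est = reversibility_bound(obs1, obs2, seed=0)
        assert est.flux_ratio == pytest.approx(52 / 17)
        assert "nad_ratio_assumed_equal" in est.flags

    def test_nad_ratio_correction_applied(self):
        obs1 = SteadyStateObservation(formaldehyde_um=50, nad_ratio=30.0, pathway="mdh_only")
        obs2 = SteadyStateObservation(formaldehyde_um=25, nad_ratio=60.0, pathway="full_pathway")
        est = reversibility_bound(obs1, obs2, seed=0)
        assert est.flux_ratio == pytest.approx(2.0 * 2.0)

    def test_zero_full_pathway_capped(self):
        obs1 = SteadyStateObservation(formaldehyde_um=50, pathway="mdh_only")
        obs2 = SteadyStateObservation(formaldehyde_um=0, pathway="full_pathway")
        est = reversibility_bound(obs1, obs2)
        assert "infinite_bound_capped" in est.flags
        assert est.forward_fraction > 0.999999


class TestPropagateUncertainty:
    def test_degenerate_when_sds_zero(self):
        prop = propagate_uncertainty(lambda x: x**2, {"x": (3.0, 0.0)}, seed=0)
        assert prop.point == prop.mean == 9.0
        assert prop.sd == 0.0

    def test_bound_interval_width_matches_delta_method(self):
        def estimator(ratio):
            r = np.asarray(ratio, dtype=float)
            return forward_fraction_from_flux_ratio(np.where(r <= 0, np.nan, r))

        mc = propagate_uncertainty(estimator, {"ratio": (1.2, 0.1)},
                                   n_samples=100000, seed=42)
        delta = propagate_uncertainty(estimator, {"ratio": (1.2, 0.1)}, method="delta")
        assert mc.interval[0] < 1.2 / 2.2 < mc.interval[1]
        assert 0.015 < mc.sd < 0.03
        assert mc.sd == pytest.approx(delta.sd, rel=0.1)

    def test_seed_reproducibility(self):
        f = lambda x: np.asarray(x) ** 2
        a = propagate_uncertainty(f, {"x": (2.0, 0.5)}, seed=7)
        b = propagate_uncertainty(f, {"x": (2.0, 0.5)}, seed=7)
        assert a.interval == b.interval and a.mean == b.mean

    def test_mostly_invalid_raises(self):
        def estimator(x):
            x = np.asarray(x, dtype=float)
            return np.where(x > 10, x, np.nan)

        with pytest.raises(ValueError, match="half"):
            propagate_uncertainty(estimator, {"x": (0.0, 1.0)}, seed=0)
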