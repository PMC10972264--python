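"""Fouling physics: area law, resistances, Darcy flux, mass balances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from anmbr import (
    CleaningParams,
    ControlParams,
    FoulingState,
    MembraneParams,
    cleaning_closed_form,
    flux_and_outflow,
    fouling_rhs_cleaning,
    fouling_rhs_filtration,
    intrinsic_resistance,
    irreversible_source_from_fraction,
    membrane_area,
    resistances,
)
from anmbr.units import flux_lhm2_to_si, flux_si_to_lhm2

MASSES = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestMembraneArea:
    def test_clean_membrane_has_initial_area(self, simple_membrane):
        assert membrane_area(FoulingState(0.0, 0.0), simple_membrane) == simple_membrane.A0

    @pytest.mark.parametrize(
        "mc,mp,expected",
        [(0.1, 0.0, 0.5), (0.0, 0.1, 0.5), (0.05, 0.05, 0.5), (0.45, 0.45, 0.1)],
    )
    def test_reciprocal_law_values(self, simple_membrane, mc, mp, expected):
        # direct evaluation of A0 / (1 + sigma*mc + sigma_prime*mp)
        assert membrane_area(FoulingState(mc, mp), simple_membrane) == pytest.approx(expected)

    def test_alternative_mass_over_sigma_form(self, simple_membrane):
        p = MembraneParams(
            **{
                **{k: getattr(simple_membrane, k) for k in (
                    "A0", "epsilon", "sigma", "sigma_prime", "alpha", "alpha_prime",
                    "R0", "delta_P", "mu_visc", "Cs", "Cx", "Csmp", "beta1", "beta2")},
                "area_form": "mass_over_sigma",
            }
        )
        assert membrane_area(FoulingState(10.0, 0.0), p) == pytest.approx(0.5)

    def test_negative_mass_rejected(self, simple_membrane):
        state = FoulingState(0.0, 0.0)
        state.mc = -1.0  # bypass constructor check
        with pytest.raises(ValueError):
            membrane_area(state, simple_membrane)

    @settings(derandomize=True, max_examples=60)
    @given(mc=MASSES, mp=MASSES)
    def test_strictly_decreasing_in_each_mass(self, simple_membrane, mc, mp):
        a = membrane_area(FoulingState(mc, mp), simple_membrane)
        assert 0.0 < a <= simple_membrane.A0
        assert membrane_area(FoulingState(mc + 0.1, mp), simple_membrane) < a
        assert membrane_area(FoulingState(mc, mp + 0.1), simple_membrane) < a


class TestResistances:
    def test_clean_membrane_has_no_fouling_resistance(self, simple_membrane):
        assert resistances(FoulingState(0, 0), 1.0, simple_membrane) == (0.0, 0.0, 0.0)

    def test_cake_only_linear(self, simple_membrane):
        rc, rp, r = resistances(FoulingState(1.0, 0.0), 1.0, simple_membrane)
        assert rc == pytest.approx(1.0e11)
        assert rp == 0.0
        assert r == pytest.approx(1.0e11)

    def test_hand_arithmetic_with_porosity(self, simple_membrane):
        rc, rp, r = resistances(FoulingState(1.0, 1.0), 0.5, simple_membrane)
        assert rc == pytest.approx(2.0e11)
        assert rp == pytest.approx(1.0e11 / 0.35)  # alpha'*mp/(eps*A)
        assert r == rc + rp

    def test_degenerate_area_rejected(self, simple_membrane):
        with pytest.raises(ValueError):
            resistances(FoulingState(1.0, 0.0), 0.0, simple_membrane)

    @settings(derandomize=True, max_examples=60)
    @given(mc=MASSES, mp=MASSES)
    def test_additivity_exact(self, simple_membrane, mc, mp):
        state = FoulingState(mc, mp)
        area = membrane_area(state, simple_membrane)
        rc, rp, r = resistances(state, area, simple_membrane)
        assert r == rc + rp


class TestFlux:
    def test_clean_water_flux(self, simple_membrane):
        j, qout = flux_and_outflow(FoulingState(0, 0), simple_membrane)
        expected = flux_si_to_lhm2(
            simple_membrane.delta_P / (simple_membrane.mu_visc * simple_membrane.R0)
        )
        assert j == pytest.approx(expected)
        assert qout == pytest.approx(j * simple_membrane.A0)

    def test_relaxation_pressure_gives_zero_flux(self, simple_membrane):
        assert flux_and_outflow(FoulingState(1, 1), simple_membrane, delta_P=0.0) == (0.0, 0.0)

    def test_flux_halves_when_fouling_resistance_equals_r0(self):
        # 1.5 bar, water-like permeate, clean flux 8.32 L/(h·m²)
        r0 = intrinsic_resistance(8.32, 1.5e5, 1.0e-3)
        p = MembraneParams(R0=r0, delta_P=1.5e5, mu_visc=1.0e-3, sigma=10.0, alpha=1.0)
        # choose mc so that R == R0 at the resulting area
        state = FoulingState(0.0, 0.0)
        j_clean, _ = flux_and_outflow(state, p)
        assert j_clean == pytest.approx(8.32, rel=1e-9)

        from scipy.optimize import brentq

        def gap(mc):
            s = FoulingState(mc, 0.0)
            area = membrane_area(s, p)
            return resistances(s, area, p)[2] - r0

        mc_half = brentq(gap, 1e-12, 1e15)
        j_half, _ = flux_and_outflow(FoulingState(mc_half, 0.0), p)
        assert j_half == pytest.approx(4.16, rel=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(mc=MASSES, mp=MASSES)
    def test_outflow_is_flux_times_area(self, simple_membrane, mc, mp):
        state = FoulingState(mc, mp)
        j, qout = flux_and_outflow(state, simple_membrane)
        assert qout == pytest.approx(j * membrane_area(state, simple_membrane), rel=1e-14)

    def test_flux_decreasing_in_resistance(self, simple_membrane):
        js = [
            flux_and_outflow(FoulingState(mc, 0.0), simple_membrane)[0]
            for mc in (0.0, 0.5, 1.0, 5.0)
        ]
        assert all(a > b for a, b in zip(js, js[1:]))


class TestUnitRoundTrip:
    @settings(derandomize=True, max_examples=30)
    @given(j=st.floats(min_value=1e-3, max_value=1e3))
    def test_flux_conversion_identity(self, j):
        assert flux_si_to_lhm2(flux_lhm2_to_si(j)) == pytest.approx(j, rel=1e-14)

    def test_conversion_factor(self):
        assert flux_si_to_lhm2(1.0) == pytest.approx(3.6e6)


class TestFoulingRhsFiltration:
    def test_no_flow_no_attachment(self, simple_membrane):
        env = {"ST": 2.0, "XT": 3.0, "SMP": 1.0, "Qout": 0.0}
        assert fouling_rhs_filtration(FoulingState(0, 0), env, simple_membrane) == (0.0, 0.0)

    def test_hand_arithmetic(self, simple_membrane):
        env = {"ST": 1.0, "XT": 1.0, "SMP": 1.0, "Qout": 1.0}
        dmc, dmp = fouling_rhs_filtration(FoulingState(0, 0), env, simple_membrane)
        assert dmc == pytest.approx(0.3)   # 1 * (0.1+0.1+0.1)
        assert dmp == pytest.approx(0.32)  # 1 * (0.3 + 0.02)

    def test_sparging_balances_attachment_at_equilibrium(self, simple_membrane):
        env = {"ST": 1.0, "XT": 1.0, "SMP": 1.0, "Qout": 1.0}
        control = ControlParams(km=5.0, kp=0.0, active=True)
        dmc, dmp = fouling_rhs_filtration(
            FoulingState(0.06, 0.0), env, simple_membrane, control
        )
        assert dmc == pytest.approx(0.0, abs=1e-12)
        assert dmp == pytest.approx(0.32)

    def test_custom_detachment_function(self, simple_membrane):
        env = {"ST": 0.0, "XT": 0.0, "SMP": 0.0, "Qout": 0.0}
        control = ControlParams(km=0.0, active=True, f=lambda m: m**2)
        dmc, _ = fouling_rhs_filtration(FoulingState(3.0, 0.0), env, simple_membrane, control)
        assert dmc == pytest.approx(-9.0)

    def test_per_component_weights(self, simple_membrane):
        from dataclasses import replace

        p = replace(simple_membrane, Cs_i=[0.2, 0.05], Cx_j=[0.3])
        env = {
            "ST": 3.0, "XT": 2.0, "SMP": 1.0, "Qout": 1.0,
            "S_i": [1.0, 2.0], "X_j": [2.0],
        }
        dmc, _ = fouling_rhs_filtration(FoulingState(0, 0), env, p)
        # 0.2*1 + 0.05*2 + 0.3*2 + 0.1*1
        assert dmc == pytest.approx(1.0)


class TestCleaning:
    def test_fixed_point_is_stationary(self):
        cp = CleaningParams(omega=12.0, omega_prime=8.0, mc_irr=0.6, mp_irr=0.4)
        state = FoulingState(0.6 / 12.0, 0.4 / 8.0)
        assert fouling_rhs_cleaning(state, cp) == pytest.approx((0.0, 0.0))

    def test_pure_decay_and_hand_value(self):
        cp = CleaningParams(omega=12.0, omega_prime=12.0, mc_irr=0.6)
        dmc, dmp = fouling_rhs_cleaning(FoulingState(1.0, 1.0), cp)
        assert dmc == pytest.approx(-11.4)
        assert dmp == pytest.approx(-12.0)

    def test_closed_form_basics(self):
        assert cleaning_closed_form(1.0, 1.0, 0.0, 0.0) == 1.0
        assert cleaning_closed_form(1.0, 1.0, 0.0, 1.0) == pytest.approx(math.exp(-1))
        assert cleaning_closed_form(1.0, 1.0, 0.0, 50.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("omega,m_irr,m0", [(12.0, 0.6, 1.0), (60.0, 0.0, 10.0), (5.0, 2.0, 0.1)])
    def test_closed_form_matches_integration(self, omega, m_irr, m0):
        cp = CleaningParams(omega=omega, omega_prime=omega, mc_irr=m_irr, mp_irr=m_irr)
        t_end = 5.0 / omega
        sol = solve_ivp(
            lambda t, y: fouling_rhs_cleaning(FoulingState(max(y[0], 0), max(y[1], 0)), cp),
            (0, t_end),
            [m0, m0],
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        ts = np.linspace(0, t_end, 20)
        expected = [cleaning_closed_form(m0, omega, m_irr, t) for t in ts]
        assert np.allclose(sol.sol(ts)[0], expected, rtol=1e-6)


class TestIrreversibleSource:
    def test_zero_fraction_needs_no_source(self):
        assert irreversible_source_from_fraction(10.0, 0.0, 60.0, 1.0) == 0.0

    def test_fraction_at_natural_decay_needs_no_source(self):
        decay = math.exp(-60.0 * (5.0 / 60.0))
        assert irreversible_source_from_fraction(10.0, decay, 60.0, 5.0 / 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_fraction(self):
        m_end, frac, omega, dur = 10.0, 0.1, 60.0, 5.0 / 60.0
        m_irr = irreversible_source_from_fraction(m_end, frac, omega, dur)
        assert cleaning_closed_form(m_end, omega, m_irr, dur) == pytest.approx(
            frac * m_end, rel=1e-10
        )

    def test_matches_root_finder_oracle(self):
        m_end, frac, omega, dur = 10.0, 0.1, 60.0, 5.0 / 60.0

        def gap(m_irr):
            return cleaning_closed_form(m_end, omega, m_irr, dur) - frac * m_end

        oracle = brentq(gap, 0.0, omega * m_end)
        assert irreversible_source_from_fraction(m_end, frac, omega, dur) == pytest.approx(
            oracle, rel=1e-10
        )


class TestIntrinsicResistance:
    def test_round_trip_with_flux(self):
        r0 = intrinsic_resistance(8.32, 1.5e5, 1.0e-3)
        p = MembraneParams(R0=r0, delta_P=1.5e5, mu_visc=1.0e-3)
        j, _ = flux_and_outflow(FoulingState(0, 0), p)
        assert j == pytest.approx(8.32, rel=1e-12)

    def test_pilot_scale_value(self):
        # 1.5 bar, 1e-3 Pa·s, 8.32 L/(h·m²) = 2.3111e-6 m/s
        assert intrinsic_resistance(8.32, 1.5e5, 1.0e-3) == pytest.approx(6.49e13, rel=1e-3)

    def test_linear_in_pressure(self):
        assert intrinsic_resistance(8.32, 3.0e5, 1.0e-3) == pytest.approx(
            2 * intrinsic_resistance(8.32, 1.5e5, 1.0e-3)
        )

    def test_nonpositive_flux_rejected(self):
        with pytest.raises(ValueError):
            intrinsic_resistance(0.0, 1.5e5, 1e-3)
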