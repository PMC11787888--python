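"""Closed-form concentration machinery vs independent ODE/series oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsrpk import (
    DomainError,
    DoseEvent,
    PKParameters,
    Regimen,
    ValidationError,
    infusion_concentration,
    periodic_steady_state,
    simulate_regimen,
    single_dose_concentration,
)

from conftest import ode_regimen_profile

MEROPENEM_PLASMA = PKParameters(volume=0.04, ka=1.34, kel=27.13)


class TestSingleDose:
    def test_zero_at_dose_instant(self):
        assert single_dose_concentration(MEROPENEM_PLASMA, 65.0, 0.0) == 0.0

    def test_peak_against_ode_oracle(self):
        # flip-flop kinetics: the slower constant (ka) is terminal
        tmax = math.log(27.13 / 1.34) / (27.13 - 1.34)
        assert tmax == pytest.approx(0.1166, abs=5e-4)
        peak = single_dose_concentration(MEROPENEM_PLASMA, 65.0, tmax)
        assert peak == pytest.approx(68.6, rel=2e-3)
        oracle = ode_regimen_profile(
            MEROPENEM_PLASMA, Regimen((DoseEvent(0.0, 65.0),), horizon=1.0),
            np.array([tmax]),
        )[0]
        assert peak == pytest.approx(oracle, abs=1e-6)

    def test_flip_flop_equivalence(self):
        """(V, ka, kel) and (V*kel/ka, kel, ka) trace the same curve, and
        the peak time is symmetric in the rate constants."""
        from hsrpk.fitting import flip_flop_alternative

        p = PKParameters(0.5, 2.0, 7.0)
        q = flip_flop_alternative(p)
        t = np.linspace(0.0, 6.0, 200)
        assert np.allclose(
            single_dose_concentration(p, 10.0, t),
            single_dose_concentration(q, 10.0, t), rtol=1e-12,
        )
        tmax = math.log(p.ka / p.kel) / (p.ka - p.kel)
        tmax_swapped = math.log(p.kel / p.ka) / (p.kel - p.ka)
        assert tmax == pytest.approx(tmax_swapped, rel=1e-12)

    def test_equal_rates_limit_form(self):
        limit = single_dose_concentration(PKParameters(1.0, 1.0, 1.0), 1.0, 1.0)
        assert limit == pytest.approx(math.exp(-1.0), rel=1e-12)
        near = single_dose_concentration(PKParameters(1.0, 1.0 + 1e-7, 1.0), 1.0, 1.0)
        assert near == pytest.approx(limit, abs=1e-6)

    def test_negative_time_and_bad_params_rejected(self):
        with pytest.raises(DomainError):
            single_dose_concentration(MEROPENEM_PLASMA, 65.0, -0.1)
        with pytest.raises(ValidationError):
            PKParameters(volume=-0.04, ka=1.34, kel=27.13)


class TestInfusion:
    def test_zero_at_start_and_derived_value(self):
        assert infusion_concentration(1.0, 0.5, 2.0, 1.0, 0.0) == 0.0
        # end-of-infusion value from the rising branch closed form
        assert infusion_concentration(1.0, 0.5, 2.0, 1.0, 1.0) == pytest.approx(
            (2.0 / 0.5) * (1.0 - math.exp(-0.5)), rel=1e-12
        )

    def test_continuity_at_end_of_infusion(self):
        eps = 1e-9
        before = infusion_concentration(0.3, 1.2, 5.0, 2.0, 2.0 - eps)
        after = infusion_concentration(0.3, 1.2, 5.0, 2.0, 2.0 + eps)
        assert before == pytest.approx(after, rel=1e-6)

    def test_fast_elimination_plateau(self):
        kel = 50.0
        plateau = (2.0 / 1.0) / (1.0 * kel)
        assert infusion_concentration(1.0, kel, 2.0, 1.0, 1.0) == pytest.approx(
            plateau, rel=1e-6
        )

    def test_against_ode_oracle(self):
        from scipy.integrate import solve_ivp

        V, kel, dose, dur = 1.0, 0.5, 2.0, 1.0

        def rhs(t, y):
            r0 = dose / dur if t < dur else 0.0
            return [r0 / V - kel * y[0]]

        sol = solve_ivp(rhs, (0, 3), [0.0], t_eval=[1.0, 3.0],
                        rtol=1e-11, atol=1e-13, max_step=0.01)
        for t, c_ode in zip(sol.t, sol.y[0]):
            assert infusion_concentration(V, kel, dose, dur, t) == pytest.approx(
                c_ode, abs=1e-6
            )


class TestSimulateRegimen:
    def test_empty_regimen_is_zero(self):
        profile = simulate_regimen(MEROPENEM_PLASMA, Regimen(()))
        t = np.linspace(0, 24, 100)
        assert np.all(profile(t) == 0)

    def test_closed_form_matches_ode_on_all_fixtures(self, drugs):
        """Superposed closed form vs two-state ODE, every drug and matrix."""
        t = np.arange(0.0, 24.0, 0.2)  # ODE oracle is slow; acceptance
        # suite re-checks on a finer grid
        for name, d in drugs.items():
            for matrix in d.matrices:
                params = d.pk_parameters(matrix)
                regimen = d.regimen(matrix)
                profile = simulate_regimen(params, regimen)
                oracle = ode_regimen_profile(params, regimen, t)
                assert np.max(np.abs(profile(t) - oracle)) < 1e-6, (name, matrix)

    def test_superposition_linearity(self, drugs):
        d = drugs["tobramycin"]
        params = d.pk_parameters("plasma")
        ev = d.regimen("plasma").events
        a, b = Regimen(ev[:2]), Regimen(ev[2:])
        both = Regimen(ev)
        t = np.arange(0, 24, 0.01)
        combined = simulate_regimen(params, a)(t) + simulate_regimen(params, b)(t)
        assert np.allclose(simulate_regimen(params, both)(t), combined,
                           rtol=0, atol=1e-10)

    def test_dose_proportionality(self, drugs):
        d = drugs["cefiderocol"]
        params = d.pk_parameters("plasma")
        regimen = d.regimen("plasma")
        t = np.arange(0, 24, 0.05)
        base = simulate_regimen(params, regimen)(t)
        scaled = simulate_regimen(params, regimen.scaled(3.0))(t)
        assert np.allclose(scaled, 3.0 * base, rtol=1e-12, atol=1e-12)

    def test_unbound_scaling_and_tagging(self, drugs):
        d = drugs["tobramycin"]
        params = d.pk_parameters("plasma")
        regimen = d.regimen("plasma")
        total = simulate_regimen(params, regimen)
        free = simulate_regimen(params, regimen, unbound_fraction=0.776)
        assert total.binding_state == "total"
        assert free.binding_state == "unbound"
        t = np.linspace(0, 24, 50)
        assert np.allclose(free(t), 0.776 * total(t), rtol=1e-12)

    def test_horizon_shorter_than_last_event_rejected(self):
        with pytest.raises(ValidationError):
            Regimen((DoseEvent(10.0, 1.0),), horizon=8.0)

    @settings(max_examples=25, deadline=None)
    @given(
        volume=st.floats(0.01, 5.0),
        ka=st.floats(0.05, 40.0),
        kel=st.floats(0.05, 40.0),
        dose=st.floats(0.1, 100.0),
    )
    def test_nonnegative_everywhere(self, volume, ka, kel, dose):
        params = PKParameters(volume=volume, ka=ka, kel=kel)
        regimen = Regimen((DoseEvent(0.0, dose), DoseEvent(3.0, dose / 2)))
        t = np.linspace(0, 24, 500)
        assert np.all(simulate_regimen(params, regimen)(t) >= 0)


class TestPeriodicSteadyState:
    def test_requires_repeat_interval(self, drugs):
        d = drugs["tobramycin"]
        with pytest.raises(ValidationError):
            periodic_steady_state(d.pk_parameters("plasma"), d.regimen("plasma"))

    def test_geometric_equals_long_simulation(self, drugs):
        for name in ("meropenem", "cefiderocol"):
            d = drugs[name]
            for matrix in d.matrices:
                params = d.pk_parameters(matrix)
                regimen = d.regimen(matrix)
                geo = periodic_steady_state(params, regimen)
                sim = periodic_steady_state(params, regimen, method="simulate")
                t = np.linspace(0, regimen.repeat_interval, 400)
                g = geo(t)
                assert np.max(np.abs(g - sim(t)) / np.maximum(g, 1e-12)) < 1e-6

    def test_cefiderocol_interval_start_carry_over(self, drugs):
        """Brute-force 10-interval accumulation fixes the trough carry-over."""
        d = drugs["cefiderocol"]
        params = d.pk_parameters("plasma")
        regimen = d.regimen("plasma")
        T = regimen.repeat_interval
        long = Regimen(regimen.events, repeat_interval=T, horizon=10 * T)
        brute = simulate_regimen(params, long, unbound_fraction=0.684)(10 * T - 1e-12)
        ss = periodic_steady_state(params, regimen, unbound_fraction=0.684)
        assert ss(0.0) == pytest.approx(brute, rel=1e-4)
        assert ss(0.0) == pytest.approx(2.2, abs=0.05)

    def test_interval_auc_identity_at_steady_state(self, drugs):
        """Steady-state AUC over one interval equals the single-course
        AUC(0, inf) — the linear-kinetics accumulation identity."""
        for name in ("meropenem", "cefiderocol"):
            d = drugs[name]
            for matrix in d.matrices:
                params = d.pk_parameters(matrix)
                regimen = d.regimen(matrix)
                ss = periodic_steady_state(params, regimen)
                single = simulate_regimen(
                    params, Regimen(regimen.events, horizon=5000.0)
                )
                assert ss.integral(0.0, regimen.repeat_interval) == pytest.approx(
                    single.integral(0.0, 5000.0), rel=1e-9
                ), (name, matrix)

    def test_fast_elimination_barely_accumulates_after_last_dose(self, drugs):
        """With e^(-slower*interval) ~ 2e-5, carry-over beyond the last dose
        of the interval is negligible relative to the fresh doses."""
        d = drugs["meropenem"]
        params = d.pk_parameters("plasma")  # slower constant 1.34/h
        regimen = d.regimen("plasma")
        slower = min(params.ka, params.kel)
        assert math.exp(-slower * regimen.repeat_interval) < 1e-4
        ss = periodic_steady_state(params, regimen)
        single = simulate_regimen(params, Regimen(regimen.events, horizon=8.0))
        t = np.linspace(6.5, 8.0, 100)  # past the interval's last dose at 6 h
        rel = np.abs(ss(t) - single(t)) / np.maximum(ss(t), 1e-9)
        assert np.max(rel) < 1e-4
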