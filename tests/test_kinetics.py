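"""Two-compartment model: closed form, ODE equivalence, schedules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnaflux import (
    CompartmentGeometry,
    CompartmentState,
    DegenerateModelError,
    FIRSeries,
    RampSegment,
    RateConstants,
    RateSchedule,
    fir_closed_form,
    fir_from_state,
    initial_state_from_fir,
    simulate_compartments,
    steady_state_fir,
    time_constant,
)
from trnaflux.kinetics import load_json, save_json

from conftest import C_FULL, C_STARVATION, FULL_NUTRITION, STARVATION


class TestClosedForm:
    def test_long_time_limit_reaches_rate_ratio(self):
        tau = time_constant(STARVATION, C_STARVATION)
        assert fir_closed_form(STARVATION, C_STARVATION, 100 * tau) == pytest.approx(3.0, abs=1e-3)

    def test_zero_at_injection_time(self):
        assert fir_closed_form(FULL_NUTRITION, C_FULL, 0.0) == 0.0
        assert fir_closed_form(STARVATION, C_STARVATION, 0.0) == 0.0

    def test_value_at_one_time_constant(self):
        # frozen by hand evaluation: (1-1/e)/(1/3 + 0.055/e)
        tau = time_constant(STARVATION, C_STARVATION)
        assert tau == pytest.approx(14.31, abs=0.01)
        assert fir_closed_form(STARVATION, C_STARVATION, tau) == pytest.approx(1.788, abs=1e-3)

    def test_agrees_with_steady_state_at_50_tau(self):
        tau = time_constant(STARVATION, C_STARVATION)
        assert fir_closed_form(STARVATION, C_STARVATION, 50 * tau) == pytest.approx(
            steady_state_fir(STARVATION), abs=1e-4
        )

    def test_no_import_gives_dark_nucleus(self):
        assert fir_closed_form(RateConstants(0.0, 0.1), 0.3, 5.0) == 0.0

    def test_degenerate_and_domain_errors(self):
        with pytest.raises(DegenerateModelError):
            fir_closed_form(RateConstants(0.0, 0.0), 0.3, 1.0)
        with pytest.raises(ValueError):
            fir_closed_form(STARVATION, C_STARVATION, -1.0)


class TestSteadyStateAndTau:
    @pytest.mark.parametrize(
        "k_in, k_out, expected",
        [(0.16, 0.10, 1.6), (0.18, 0.08, 2.25), (0.25, 0.25, 1.0)],
    )
    def test_plateau_is_rate_ratio(self, k_in, k_out, expected):
        assert steady_state_fir(RateConstants(k_in, k_out)) == pytest.approx(expected)

    def test_no_export_is_unbounded(self):
        with pytest.raises(DegenerateModelError):
            steady_state_fir(RateConstants(0.1, 0.0))

    @pytest.mark.parametrize(
        "k_in, k_out, c, expected, tol",
        [
            (0.30, 0.32, 0.322, 2.40, 0.01),
            (0.0, 0.25, 0.5, 4.0, 1e-12),   # pure first-order decay, 1/k_out
            (0.18, 0.06, 0.055, 14.31, 0.01),
        ],
    )
    def test_time_constant_formula(self, k_in, k_out, c, expected, tol):
        assert time_constant(RateConstants(k_in, k_out), c) == pytest.approx(expected, abs=tol)

    def test_time_constant_degenerate(self):
        with pytest.raises(DegenerateModelError):
            time_constant(RateConstants(0.0, 0.0), 0.3)


class TestGeometryAndState:
    def test_composite_is_phi_over_w(self):
        g = CompartmentGeometry(V_N=2.0, V_C=10.0, w=0.5)
        assert g.phi == pytest.approx(0.2)
        assert g.c == pytest.approx(0.4)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CompartmentGeometry(V_N=-1, V_C=1)
        with pytest.raises(ValueError):
            CompartmentGeometry(V_N=1, V_C=1, w=1.5)

    def test_fir_from_state(self):
        assert fir_from_state(CompartmentState(0, 2.0, 1.0, 1.0)) == 2.0
        assert fir_from_state(CompartmentState(0, 0.0, 1.0, 1.0)) == 0.0
        with pytest.raises(ZeroDivisionError):
            fir_from_state(CompartmentState(0, 1.0, 0.0, 0.0))


class TestSimulation:
    def test_constant_rates_match_closed_form(self, starvation_geom):
        times = np.linspace(0.5, 120, 100)
        init = CompartmentState(0, 0.0, 1.0, 1.0)
        states = simulate_compartments(STARVATION, starvation_geom, init, times)
        fir_ode = np.array([fir_from_state(s) for s in states])
        np.testing.assert_allclose(
            fir_ode, fir_closed_form(STARVATION, C_STARVATION, times), atol=1e-6
        )

    def test_conservation_under_ramp(self):
        geom = CompartmentGeometry(V_N=0.32, V_C=1.0, w=0.8)
        sched = RateSchedule.media_switch(FULL_NUTRITION, STARVATION)
        init = CompartmentState(0, 0.5, 1.0, 0.8)
        states = simulate_compartments(sched, geom, init, np.linspace(1, 60, 40))
        total0 = geom.V_N * init.C_N + geom.V_C * init.C_bar_C
        totals = np.array([geom.V_N * s.C_N + geom.V_C * s.C_bar_C for s in states])
        np.testing.assert_allclose(totals, total0, rtol=1e-8)

    def test_deprivation_switch_crosses_unity_within_10_min(self):
        """Switching fed cells to starvation rates pushes FIR past 1 in <10 min."""
        sched = RateSchedule.media_switch(FULL_NUTRITION, STARVATION, ramp_duration=25.0)
        geom = CompartmentGeometry.from_composite(C_FULL)
        init = initial_state_from_fir(0.7, geom)
        states = simulate_compartments(sched, geom, init, [5.0, 10.0])
        assert fir_from_state(states[-1]) > 1.0

    def test_refeeding_relaxes_monotonically_toward_unity(self):
        """Starved cells given full medium export tRNA: FIR decays toward k_in/k_out."""
        sched = RateSchedule.media_switch(STARVATION, FULL_NUTRITION, ramp_duration=25.0)
        geom = CompartmentGeometry.from_composite(C_FULL)
        init = initial_state_from_fir(3.0, geom)
        states = simulate_compartments(sched, geom, init, np.linspace(1, 120, 60))
        fir = np.array([fir_from_state(s) for s in states])
        # nonincreasing up to integrator round-off at the plateau
        assert np.all(np.diff(fir) < 1e-6)
        assert fir[-1] == pytest.approx(steady_state_fir(FULL_NUTRITION), abs=0.01)

    def test_quasi_steady_state_matches_plateau(self):
        rates = RateConstants(0.16, 0.10)
        geom = CompartmentGeometry.from_composite(0.1)
        init = CompartmentState(0, 0.0, 1.0, 1.0)
        (state,) = simulate_compartments(rates, geom, init, [100 * time_constant(rates, 0.1)])
        assert fir_from_state(state) == pytest.approx(1.6, abs=1e-3)

    def test_monotone_increase_bounded_by_plateau(self):
        init = CompartmentState(0, 0.0, 1.0, 1.0)
        states = simulate_compartments(STARVATION, CompartmentGeometry.from_composite(0.2),
                                       init, np.linspace(0.5, 200, 120))
        fir = np.array([fir_from_state(s) for s in states])
        assert np.all(np.diff(fir) > 0)
        assert np.all(fir < steady_state_fir(STARVATION))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(-0.1, 0.2)
        with pytest.raises(ValueError):
            RateSchedule(STARVATION, (RampSegment(0.0, STARVATION, "linear", -5.0),))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    k_in=st.floats(0.01, 1.0),
    k_out=st.floats(0.01, 1.0),
    c=st.floats(0.05, 1.0),
)
def test_ode_equals_closed_form_for_random_parameters(k_in, k_out, c):
    """Numerical integration and the closed form are the same model."""
    rates = RateConstants(k_in, k_out)
    tau = time_constant(rates, c)
    times = np.linspace(0.01, 100 * tau, 40)
    init = CompartmentState(0, 0.0, 1.0, 1.0)
    states = simulate_compartments(rates, CompartmentGeometry.from_composite(c), init, times)
    fir_ode = np.array([fir_from_state(s) for s in states])
    np.testing.assert_allclose(fir_ode, fir_closed_form(rates, c, times), atol=1e-6)


class TestSerialization:
    def test_fir_series_csv_roundtrip(self, tmp_path):
        s = FIRSeries(np.arange(5.0), np.array([0, 0.5, 1.0, 1.2, 1.3]),
                      sigma=np.full(5, 0.1))
        p = tmp_path / "fir.csv"
        s.to_csv(p)
        back = FIRSeries.from_csv(p)
        np.testing.assert_allclose(back.times, s.times)
        np.testing.assert_allclose(back.fir, s.fir)
        np.testing.assert_allclose(back.sigma, s.sigma)

    def test_schedule_json_roundtrip(self, tmp_path):
        sched = RateSchedule.media_switch(FULL_NUTRITION, STARVATION, switch_time=30.0)
        p = tmp_path / "sched.json"
        save_json(sched, p)
        back = load_json(p)
        assert back.rates_at(29.9) == FULL_NUTRITION
        assert back.rates_at(55.1) == STARVATION
        mid = back.rates_at(42.5)  # halfway through the ramp
        assert mid.k_in == pytest.approx(0.24)
        assert mid.k_out == pytest.approx(0.19)

    def test_series_validation(self):
        with pytest.raises(ValueError):
            FIRSeries(np.array([2.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            FIRSeries(np.array([0.0, 1.0]), np.array([0.1, -0.2]))
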