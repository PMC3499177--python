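"""Two-compartment PK: closed form, ODE path, metrics, and fitting."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import pk_ode_oracle, random_pk_params
from xenopkpd import synthetic as syn
from xenopkpd.pk import (
    DoseEvent,
    DoseRegimen,
    PKParams,
    closed_form_concentration,
    fit_pk,
    pk_metrics,
    regimen_concentration,
    scale_dose_proportional,
    simulate_pk_profile,
)

BATEMAN = PKParams(ka=1.0, Vc=10.0, CL=1.0, Q=0.0, Vp=1.0)  # ke = 0.1 1/h


def bateman_analytic(t, D=100.0, ka=1.0, ke=0.1, Vc=10.0):
    return D * ka / (Vc * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


class TestParamsAndRegimen:
    @pytest.mark.parametrize("bad", [
        dict(ka=-1.0, Vc=1.0, CL=1.0), dict(ka=1.0, Vc=0.0, CL=1.0),
        dict(ka=1.0, Vc=1.0, CL=1.0, Q=-0.1), dict(ka=1.0, Vc=1.0, CL=1.0, F=1.5),
        dict(ka=math.nan, Vc=1.0, CL=1.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            PKParams(**bad)

    def test_daily_clearance_conversion(self):
        p = PKParams.from_daily_clearance(0.54, 2.61, 3.11)
        assert p.CL == pytest.approx(3.11 / 24.0)
        assert p.CL_mL_per_day == pytest.approx(3.11)

    def test_regimen_sorts_and_merges_equal_times(self):
        reg = DoseRegimen((DoseEvent(84.0, 20.0), DoseEvent(0.0, 20.0),
                           DoseEvent(84.0, 10.0)))
        assert [ev.time for ev in reg.events] == [0.0, 84.0]
        assert reg.events[1].amount == 30.0

    def test_twice_weekly_patterns(self):
        uni = DoseRegimen.twice_weekly(20.0, 4)
        assert list(uni.times) == [0.0, 84.0, 168.0, 252.0]
        alt = DoseRegimen.twice_weekly(20.0, 4, pattern="3-4")
        assert list(alt.times) == [0.0, 72.0, 168.0, 240.0]

    def test_dose_event_validation(self):
        with pytest.raises(ValueError, match="time"):
            DoseEvent(-1.0, 5.0)
        with pytest.raises(ValueError, match="amount"):
            DoseEvent(0.0, 0.0)


class TestClosedFormAndSimulation:
    def test_concentration_zero_at_dose_time(self, printed_pk):
        # absorption-only input: the central compartment is empty at t = 0
        reg = DoseRegimen.single(100.0)
        assert closed_form_concentration(printed_pk, reg.events[0], 0.0) == 0.0
        tc = simulate_pk_profile(printed_pk, reg, [0.0, 1.0])
        assert tc.concentrations[0] == 0.0

    def test_one_compartment_limit_is_bateman(self):
        t = np.linspace(0.0, 100.0, 300)
        expected = bateman_analytic(t)
        got = closed_form_concentration(BATEMAN, DoseEvent(0.0, 100.0), t)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-15)
        assert closed_form_concentration(BATEMAN, DoseEvent(0.0, 100.0), 5.0) == \
            pytest.approx(bateman_analytic(5.0), rel=1e-12)

    def test_ode_matches_bateman(self):
        tc = simulate_pk_profile(BATEMAN, DoseRegimen.single(100.0), [5.0])
        assert tc.concentrations[0] == pytest.approx(bateman_analytic(5.0), rel=1e-8)

    def test_two_compartment_single_dose_vs_oracle(self, printed_pk):
        reg = DoseRegimen.single(500.0)
        t = np.array([24.0])
        got = simulate_pk_profile(printed_pk, reg, t).concentrations
        expected = pk_ode_oracle(printed_pk, reg, t)
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_closed_form_matches_ode_on_random_params(self):
        rng = np.random.default_rng(11)
        reg = DoseRegimen.single(200.0)
        t = np.array([1.0, 6.0, 24.0, 72.0, 168.0, 336.0])
        for _ in range(5):
            p = random_pk_params(rng)
            cf = closed_form_concentration(p, reg.events[0], t)
            ode = simulate_pk_profile(p, reg, t).concentrations
            np.testing.assert_allclose(ode, cf, rtol=1e-6)

    def test_degenerate_bateman_limit_branch(self):
        # ka == ke resolved by the t*ka*exp(-ka*t) limit, continuous with nearby ka
        ke = 0.1
        p_eq = PKParams(ka=ke, Vc=10.0, CL=1.0, Q=0.0, Vp=1.0)
        p_near = PKParams(ka=ke * (1 + 1e-7), Vc=10.0, CL=1.0, Q=0.0, Vp=1.0)
        t = np.linspace(0.1, 50.0, 50)
        d = DoseEvent(0.0, 100.0)
        exact = 100.0 / 10.0 * ke * t * np.exp(-ke * t)
        np.testing.assert_allclose(closed_form_concentration(p_eq, d, t), exact, rtol=1e-12)
        np.testing.assert_allclose(closed_form_concentration(p_near, d, t), exact, rtol=1e-5)
        with pytest.raises(ValueError, match="coincidence"):
            closed_form_concentration(p_eq, d, t, degenerate="raise")

    def test_multi_dose_superposition_identity(self, printed_pk):
        reg = DoseRegimen((DoseEvent(0.0, 100.0), DoseEvent(84.0, 100.0)))
        t = np.linspace(1.0, 336.0, 40)
        two = regimen_concentration(printed_pk, reg, t)
        a = closed_form_concentration(printed_pk, DoseEvent(0.0, 100.0), t)
        b = closed_form_concentration(printed_pk, DoseEvent(84.0, 100.0), t)
        np.testing.assert_allclose(two, a + b, rtol=1e-12)
        ode = simulate_pk_profile(printed_pk, reg, t).concentrations
        np.testing.assert_allclose(ode, two, rtol=1e-6)

    def test_invalid_times_rejected(self, printed_pk):
        reg = DoseRegimen.single(1.0)
        with pytest.raises(ValueError, match=">= 0"):
            simulate_pk_profile(printed_pk, reg, [-1.0, 2.0])
        with pytest.raises(ValueError, match="increasing"):
            simulate_pk_profile(printed_pk, reg, [2.0, 1.0])

    def test_mass_balance_full_state(self, printed_pk):
        reg = DoseRegimen.twice_weekly(500.0, 3)
        t = np.linspace(1.0, 336.0, 30)
        _, states = simulate_pk_profile(printed_pk, reg, t, return_states=True)
        dosed = np.array([printed_pk.F * sum(ev.amount for ev in reg.events
                                             if ev.time <= ti) for ti in t])
        np.testing.assert_allclose(states.sum(axis=1), dosed, rtol=1e-6)


class TestMetrics:
    def test_all_zero_curve(self, printed_pk):
        tc = simulate_pk_profile(printed_pk, DoseRegimen(()), np.linspace(0, 84, 100))
        m = pk_metrics(tc, printed_pk, DoseEvent(0.0, 100.0))
        assert m.cmax == 0.0 and m.auc_first_dose == 0.0

    def test_auc_inf_is_dose_over_clearance(self):
        p = PKParams.from_daily_clearance(0.5, 2.0, 3.11)
        tc = simulate_pk_profile(p, DoseRegimen.single(311.0), np.linspace(0, 10, 5)[1:])
        m = pk_metrics(tc, p, DoseEvent(0.0, 311.0))
        assert m.auc_inf_single == pytest.approx(100.0)

    def test_trapezoid_auc_approaches_analytic(self):
        t = np.arange(0.0, 120.0 + 1e-9, 0.01)
        tc = simulate_pk_profile(BATEMAN, DoseRegimen.single(100.0), t[1:])
        m = pk_metrics(tc, BATEMAN, DoseEvent(0.0, 100.0))
        assert m.auc_first_dose == pytest.approx(m.auc_inf_single, rel=5e-3)

    def test_cmax_bounds_every_concentration(self, printed_pk):
        t = np.linspace(0.5, 336.0, 400)
        tc = simulate_pk_profile(printed_pk, DoseRegimen.twice_weekly(200.0, 4), t)
        m = pk_metrics(tc, printed_pk, DoseEvent(0.0, 200.0))
        assert np.all(m.cmax >= tc.concentrations)

    def test_empty_timecourse_rejected(self, printed_pk):
        from xenopkpd.pk import ConcentrationTimecourse
        with pytest.raises(ValueError, match="empty"):
            pk_metrics(ConcentrationTimecourse(np.array([]), np.array([])),
                       printed_pk, DoseEvent(0.0, 1.0))


class TestDoseProportionality:
    @pytest.mark.parametrize("value, ref, target, expected", [
        (30.2, 20.0, 500.0, 755.0),   # AUC scaling across the study dose range
        (12.2, 20.0, 500.0, 305.0),   # Cmax scaling across the study dose range
        (42.0, 200.0, 200.0, 42.0),   # identity at the same dose
    ])
    def test_linear_scaling(self, value, ref, target, expected):
        assert scale_dose_proportional(value, ref, target) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_doses(self):
        with pytest.raises(ValueError):
            scale_dose_proportional(1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            scale_dose_proportional(1.0, 10.0, -1.0)

    @given(dose=st.floats(1.0, 1000.0), factor=st.floats(0.1, 50.0))
    def test_simulated_concentrations_scale_exactly_with_dose(self, dose, factor):
        p = PKParams.from_daily_clearance(0.54, 2.61, 3.11)
        t = np.array([6.0, 24.0, 96.0])
        base = closed_form_concentration(p, DoseEvent(0.0, dose), t)
        scaled = closed_form_concentration(p, DoseEvent(0.0, dose * factor), t)
        np.testing.assert_allclose(scaled, base * factor, rtol=1e-9)


class TestFitPK:
    def test_noise_free_recovery(self, truth):
        design = syn.StudyDesign(seed=2).noise_free()
        data = syn.generate_pk_dataset(truth, design)
        regimens = {d: design.regimen(d) for d in design.pk_doses}
        fit = fit_pk(data, regimens, truth.pk)
        assert fit.converged
        for name in ("ka", "Vc", "CL"):
            assert fit.estimates[name] == pytest.approx(getattr(truth.pk, name), rel=1e-2)
        assert fit.standard_errors is not None

    def test_single_timepoint_is_underdetermined(self, truth):
        df = pd.DataFrame({
            "animal_id": [f"m{i}" for i in range(5)],
            "dose_group_ug": 20.0, "time_h": 24.0,
            "conc_ug_per_ml": [3.1, 2.9, 3.3, 3.0, 2.8], "below_lloq": 0,
        })
        with pytest.raises(ValueError, match="under-determined"):
            fit_pk(df, {20.0: DoseRegimen.single(20.0)}, truth.pk)

    def test_all_censored_rejected(self, truth):
        df = pd.DataFrame({
            "animal_id": ["a"] * 8, "dose_group_ug": 20.0,
            "time_h": np.arange(8.0) * 24 + 24, "conc_ug_per_ml": 0.01,
            "below_lloq": 1,
        })
        with pytest.raises(ValueError, match="censored"):
            fit_pk(df, {20.0: DoseRegimen.single(20.0)}, truth.pk)

    def test_censored_points_excluded_from_objective(self, truth):
        design = syn.StudyDesign(seed=4).noise_free()
        data = syn.generate_pk_dataset(truth, design)
        regimens = {d: design.regimen(d) for d in design.pk_doses}
        # corrupt some values but flag them censored: the fit must be unchanged
        spoiled = data.copy()
        idx = spoiled.index[:10]
        spoiled.loc[idx, "conc_ug_per_ml"] = 1e-4
        spoiled.loc[idx, "below_lloq"] = 1
        f1 = fit_pk(data, regimens, truth.pk, n_starts=1)
        f2 = fit_pk(spoiled, regimens, truth.pk, n_starts=1)
        assert f2.estimates["CL"] == pytest.approx(f1.estimates["CL"], rel=1e-6)
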