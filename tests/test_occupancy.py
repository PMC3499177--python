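"""Competitive binding, standard curve, and Kd estimation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import binding_equilibrium_oracle
from xenopkpd import synthetic as syn
from xenopkpd.occupancy import (
    CompetitionPoint,
    OccupancyParams,
    STANDARD_COMPETITOR_NM,
    build_standard_curve,
    competitive_labeled_fraction,
    fit_kd,
    invert_standard_curve,
    nM_from_ug_per_mL,
    occupancy_fraction,
)


class TestOccupancyFraction:
    @pytest.mark.parametrize("C, kd, smax, expected", [
        (0.0, 0.9, 100.0, 0.0),
        (0.9, 0.9, 100.0, 50.0),      # half-maximal at C = Kd by definition
        (8.1, 0.9, 100.0, 90.0),      # C = 9*Kd
        (0.5, 0.5, 80.0, 40.0),
    ])
    def test_closed_form_values(self, C, kd, smax, expected):
        assert occupancy_fraction(C, OccupancyParams(kd, smax)) == pytest.approx(expected)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            occupancy_fraction(-0.1, OccupancyParams(0.9))

    @given(c1=st.floats(0.01, 100.0), c2=st.floats(0.01, 100.0),
           kd1=st.floats(0.01, 10.0), kd2=st.floats(0.01, 10.0))
    def test_monotone_in_concentration_and_kd(self, c1, c2, kd1, kd2):
        p = OccupancyParams(kd1)
        if c1 != c2:
            lo, hi = sorted([c1, c2])
            assert occupancy_fraction(lo, p) < occupancy_fraction(hi, p)
        if kd1 != kd2:
            lo, hi = sorted([kd1, kd2])
            assert occupancy_fraction(c1, OccupancyParams(hi)) < \
                occupancy_fraction(c1, OccupancyParams(lo))

    def test_molar_bridge(self):
        assert nM_from_ug_per_mL(1.0) == pytest.approx(6.8)
        assert OccupancyParams(0.922).Kd_ug_per_mL == pytest.approx(0.922 / 6.8)


class TestCompetitiveBinding:
    def test_limits(self):
        assert competitive_labeled_fraction(1e6, 0.0, 0.9) == pytest.approx(1.0, abs=1e-5)
        assert competitive_labeled_fraction(3.0, 3.0, 1e-12) == pytest.approx(0.5)
        assert competitive_labeled_fraction(0.0, 5.0, 0.9) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            competitive_labeled_fraction(-1.0, 0.0, 0.9)

    def test_against_depletion_aware_equilibrium_oracle(self):
        # assay regime: receptor density far below antibody concentrations
        got = competitive_labeled_fraction(6.8, 17.0, 0.9)
        expected = binding_equilibrium_oracle(6.8, 17.0, 0.9, R_total=1e-4)
        assert got == pytest.approx(expected, abs=1e-4)

    def test_depletion_matters_at_high_receptor_density(self):
        # sanity of the oracle itself: depletion lowers the labeled-bound fraction
        low = binding_equilibrium_oracle(1.0, 1.0, 0.9, R_total=1e-6)
        high = binding_equilibrium_oracle(1.0, 1.0, 0.9, R_total=5.0)
        assert high < low

    @given(L=st.floats(0.1, 50.0), U=st.floats(0.0, 50.0), kd=st.floats(0.05, 10.0))
    def test_bound_fractions_sum_to_one(self, L, U, kd):
        fl = competitive_labeled_fraction(L, U, kd)
        fu = competitive_labeled_fraction(U, L, kd)  # symmetric roles
        free = kd / (L + U + kd)
        assert fl + fu + free == pytest.approx(1.0, abs=1e-12)

    @given(L=st.floats(0.5, 20.0), kd=st.floats(0.05, 5.0),
           u1=st.floats(0.0, 30.0), u2=st.floats(0.0, 30.0))
    def test_monotone_in_competitor(self, L, kd, u1, u2):
        if u1 != u2:
            lo, hi = sorted([u1, u2])
            assert competitive_labeled_fraction(L, hi, kd) < \
                competitive_labeled_fraction(L, lo, kd)


def _series_from_model(kd=0.922, L=6.8, concs=STANDARD_COMPETITOR_NM, r0=0.85):
    return [CompetitionPoint(U, r0 * competitive_labeled_fraction(L, U, kd) /
                             competitive_labeled_fraction(L, 0.0, kd), L)
            for U in concs]


class TestStandardCurve:
    def test_flat_ratios_give_zero_saturation(self):
        pts = [CompetitionPoint(U, 0.8) for U in (0.0, 1.0, 10.0)]
        curve = build_standard_curve(pts)
        assert np.allclose(curve.saturations, 0.0)

    def test_round_trip_on_knots_is_identity(self):
        pts = _series_from_model()
        curve = build_standard_curve(pts)
        for r, s in zip(curve.ratios, curve.saturations):
            assert invert_standard_curve(curve, r) == pytest.approx(s, abs=1e-9)
        assert invert_standard_curve(curve, curve.ratio0) == pytest.approx(0.0, abs=1e-12)

    def test_curve_reproduces_generating_saturations(self):
        kd, L = 0.922, 6.8
        curve = build_standard_curve(_series_from_model(kd, L))
        # saturation by unlabeled antibody implied by the competition model
        expected = [100.0 * (1.0 - (L + kd) / (L + U + kd)) for U in curve.concs]
        np.testing.assert_allclose(curve.saturations, expected, atol=1e-9)

    def test_off_grid_inversion_close_to_model(self):
        kd, L = 0.922, 6.8
        curve = build_standard_curve(_series_from_model(kd, L))
        U_off = 3.0  # between grid points
        r_off = 0.85 * (L + kd) / (L + U_off + kd)
        sat_model = 100.0 * (1.0 - (L + kd) / (L + U_off + kd))
        assert invert_standard_curve(curve, r_off) == pytest.approx(sat_model, abs=2.0)

    def test_two_points_insufficient(self):
        with pytest.raises(ValueError, match="insufficient"):
            build_standard_curve([CompetitionPoint(0.0, 0.8), CompetitionPoint(1.0, 0.5)])

    def test_missing_zero_anchor_rejected(self):
        pts = [CompetitionPoint(U, 0.8 / (1 + U)) for U in (0.21, 0.63, 1.83)]
        with pytest.raises(ValueError, match="anchor"):
            build_standard_curve(pts)

    def test_non_monotone_beyond_tolerance_rejected(self):
        pts = [CompetitionPoint(0.0, 0.80), CompetitionPoint(0.5, 0.60),
               CompetitionPoint(1.0, 0.75), CompetitionPoint(5.0, 0.30)]
        with pytest.raises(ValueError, match="not monotone"):
            build_standard_curve(pts)

    def test_out_of_span_ratio_clamped_with_warning(self):
        curve = build_standard_curve(_series_from_model())
        with pytest.warns(UserWarning, match="clamped"):
            sat = invert_standard_curve(curve, curve.ratio0 * 1.5)
        assert sat == pytest.approx(0.0, abs=1e-9)


class TestFitKd:
    def test_noise_free_direct_route(self):
        truth = OccupancyParams(Kd=0.9)
        conc = np.array([0.1, 0.21, 0.63, 1.83, 5.64, 17.0])
        fit = fit_kd((conc, occupancy_fraction(conc, truth)),
                     OccupancyParams(Kd=0.3))
        assert fit.converged
        assert fit.estimates["Kd"] == pytest.approx(0.9, rel=1e-3)

    def test_noise_free_competition_route_recovers_generating_kd(self, truth):
        design = syn.StudyDesign(seed=9).noise_free()
        invitro, _ = syn.generate_saturation_dataset(truth, design)
        fit = fit_kd(invitro, OccupancyParams(Kd=0.3))
        assert fit.converged
        assert fit.estimates["Kd"] == pytest.approx(truth.occupancy.Kd, rel=1e-3)

    def test_monte_carlo_bias_small_under_additive_noise(self):
        truth = OccupancyParams(Kd=0.9)
        conc = np.array([0.21, 0.63, 1.83, 5.64, 17.0])
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            sat = occupancy_fraction(conc, truth) + rng.normal(0.0, 5.0, conc.size)
            fit = fit_kd((conc, np.clip(sat, 0.0, 100.0)), truth)
            errs.append(abs(fit.estimates["Kd"] - 0.9) / 0.9)
        assert np.median(errs) < 0.10

    def test_all_zero_saturations_rejected(self):
        conc = np.array([0.2, 1.0, 5.0])
        with pytest.raises(ValueError, match="zero"):
            fit_kd((conc, np.zeros(3)), OccupancyParams(Kd=1.0))

    def test_saturated_design_flagged_non_identifiable(self):
        # every concentration far above Kd: the readout is flat at Smax
        conc = np.array([100.0, 200.0, 400.0, 800.0])
        fit = fit_kd((conc, np.full(4, 100.0)), OccupancyParams(Kd=1.0))
        assert not fit.converged
        assert "non-identifiable" in fit.message
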