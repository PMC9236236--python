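"""Unit and property tests for the doubly-labeled-water computation chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zooenergetics import dlw
from zooenergetics.dlw import DlwError


class TestKineticsFit:
    def test_two_point_fit_is_exact_line(self):
        # hand log-linear solution: k = ln(600/250)/(7 - 0.27)
        fit = dlw.fit_isotope_kinetics([0.27, 7.0], [600.0, 250.0])
        k = math.log(600.0 / 250.0) / 6.73
        assert fit.k == pytest.approx(k, rel=1e-12)
        assert fit.intercept_excess == pytest.approx(600.0 * math.exp(k * 0.27), rel=1e-10)
        assert fit.r_squared == 1.0

    def test_noiseless_exponential_recovered_exactly(self):
        t = np.array([0.5, 2.0, 4.0, 7.0])
        e = 500.0 * np.exp(-0.1 * t)
        fit = dlw.fit_isotope_kinetics(t, e)
        assert fit.k == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept_excess == pytest.approx(500.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle_with_noise(self):
        rng = np.random.default_rng(42)
        t = np.array([0.3, 1.0, 7.0])
        e = 480.0 * np.exp(-0.12 * t) * np.exp(rng.normal(0, 0.01, 3))
        fit = dlw.fit_isotope_kinetics(t, e)
        # brute-force normal equations for ln(e) = a + b t
        y = np.log(e)
        n = len(t)
        b = (n * (t * y).sum() - t.sum() * y.sum()) / (n * (t * t).sum() - t.sum() ** 2)
        a = (y.sum() - b * t.sum()) / n
        assert fit.k == pytest.approx(-b, abs=1e-12)
        assert fit.intercept_excess == pytest.approx(math.exp(a), rel=1e-12)

    def test_hours_accepted_and_converted(self):
        t_days = np.array([0.25, 3.0, 7.0])
        e = 500.0 * np.exp(-0.1 * t_days)
        fit = dlw.fit_isotope_kinetics(t_days * 24.0, e, time_unit="hours")
        assert fit.k == pytest.approx(0.1, abs=1e-12)

    def test_background_is_subtracted_before_fit(self):
        t = np.array([0.5, 3.0, 6.0])
        excess = 400.0 * np.exp(-0.2 * t)
        fit = dlw.fit_isotope_kinetics(t, excess + 150.0, background=150.0)
        assert fit.k == pytest.approx(0.2, abs=1e-12)

    @pytest.mark.parametrize(
        "times, enrich, msg",
        [
            ([1.0], [300.0], "insufficient samples"),
            ([1.0, 1.0], [300.0, 290.0], "insufficient samples"),
            ([0.5, 2.0], [300.0, 100.0], "below background"),
        ],
    )
    def test_invalid_series_rejected(self, times, enrich, msg):
        with pytest.raises(DlwError, match=msg):
            dlw.fit_isotope_kinetics(times, enrich, background=150.0)


class TestDilutionSpaces:
    def test_space_is_dose_equivalent_over_intercept(self):
        assert dlw.dilution_space_from_equivalent(1.0e8, 500.0) == pytest.approx(2.0e5)

    def test_doubling_intercept_halves_space(self):
        n1 = dlw.dilution_space_from_equivalent(1.0e8, 500.0)
        n2 = dlw.dilution_space_from_equivalent(1.0e8, 1000.0)
        assert n2 == pytest.approx(n1 / 2)

    def test_nonpositive_intercept_rejected(self):
        with pytest.raises(DlwError):
            dlw.dilution_space_from_equivalent(1.0e8, 0.0)

    def test_pooled_space_formula(self):
        spaces = dlw.pooled_dilution_space(100.0, 100.0)
        assert spaces.N_pooled == pytest.approx((100 / 1.007 + 100 / 1.043) / 2)
        assert spaces.N_pooled == pytest.approx(97.59108, abs=1e-5)
        assert spaces.ratio == 1.0

    def test_pooled_space_constants_cancel(self):
        assert dlw.pooled_dilution_space(1.043, 1.007).N_pooled == pytest.approx(1.0)

    def test_dilution_space_ratio_reported(self):
        # the study female's dilution-space ratio
        spaces = dlw.pooled_dilution_space(1.043 * 320.0, 320.0)
        assert spaces.ratio == pytest.approx(1.043)

    def test_nonpositive_spaces_rejected(self):
        with pytest.raises(DlwError):
            dlw.pooled_dilution_space(-1.0, 100.0)


class TestBodyWaterAndComposition:
    def test_tbw_constant(self):
        assert dlw.total_body_water(1000.0) == pytest.approx(18.02)

    def test_tbw_inverse_identity(self):
        assert dlw.total_body_water(324.97) / 0.01802 == pytest.approx(324.97)

    def test_tbw_rejects_nonpositive(self):
        with pytest.raises(DlwError):
            dlw.total_body_water(0.0)

    def test_composition_arithmetic(self):
        comp = dlw.body_composition(5.856, 9.7)
        assert comp.FFM == pytest.approx(8.0, abs=1e-12)
        assert comp.FM == pytest.approx(1.7, abs=1e-12)
        assert comp.pct_fat == pytest.approx(100 * 1.7 / 9.7, abs=1e-9)
        assert comp.consistent

    def test_fully_hydrated_boundary_has_zero_fat(self):
        comp = dlw.body_composition(0.732 * 9.0, 9.0)
        assert comp.FM == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_pair_flagged_not_raised(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            comp = dlw.body_composition(8.0, 9.0)  # FFM = 10.9 > 9.0
        assert not comp.consistent
        assert comp.FM < 0


class TestRco2:
    def test_direct_arithmetic_example(self):
        # 300 * (1.007*0.15 - 1.043*0.10) * (1/2.078 - 0.0246*1.05)
        assert dlw.rco2(300.0, 0.10, 0.15) == pytest.approx(
            300.0 * 0.04675 * (1.0 / 2.078 - 0.02583), rel=1e-12
        )
        assert dlw.rco2(300.0, 0.10, 0.15) == pytest.approx(6.387, abs=5e-3)

    def test_boundary_turnover_rejected(self):
        with pytest.raises(DlwError, match="non-physiological"):
            dlw.rco2(300.0, 0.10, (1.043 / 1.007) * 0.10)

    def test_linear_in_pool_size(self):
        assert dlw.rco2(600.0, 0.10, 0.15) == pytest.approx(2 * dlw.rco2(300.0, 0.10, 0.15))

    @given(
        n=st.floats(10.0, 1e4),
        k_d=st.floats(0.01, 0.5),
        excess=st.floats(0.001, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_algebraic_identity(self, n, k_d, excess):
        k_o = (1.043 * k_d + excess) / 1.007
        expected = n * excess * (1.0 / 2.078 - 0.0246 * 1.05)
        assert dlw.rco2(n, k_d, k_o) == pytest.approx(expected, rel=1e-12)


class TestFoodQuotientAndWeir:
    def test_all_carbohydrate_diet(self):
        assert dlw.food_quotient(0.0, 50.0, 100.0, 0.0).FQ == 1.0

    def test_all_fat_diet(self):
        assert dlw.food_quotient(0.0, 0.0, 0.0, 80.0).FQ == pytest.approx(0.7)

    def test_zero_total_rejected(self):
        with pytest.raises(DlwError):
            dlw.food_quotient(0.0, 0.0, 0.0, 0.0)

    @given(
        cp=st.floats(0, 500), ndf=st.floats(0, 500),
        tnc=st.floats(0, 500), cf=st.floats(0, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_fq_bounded_by_oxidation_coefficients(self, cp, ndf, tnc, cf):
        if cp + ndf + tnc + cf <= 0:
            return
        fq = dlw.food_quotient(cp, ndf, tnc, cf).FQ
        present = [c for c, me in [(0.8, cp), (1.0, ndf + tnc), (0.7, cf)] if me > 0]
        assert min(present) - 1e-12 <= fq <= max(present) + 1e-12

    def test_weir_at_unit_fq(self):
        assert dlw.weir_tee(1.0, 1.0) == pytest.approx(22.26 * 5.046, rel=1e-12)

    def test_weir_monotone_decreasing_in_fq(self):
        tees = [dlw.weir_tee(2.0, fq) for fq in (0.8, 0.9, 1.0)]
        assert tees[0] > tees[1] > tees[2]

    def test_weir_rejects_bad_fq(self):
        with pytest.raises(DlwError):
            dlw.weir_tee(2.0, 0.0)


class TestEnergyScaling:
    def test_kj_conversion_exact_before_rounding(self):
        e = dlw.scale_energy(288.0, 9.7)
        assert e.tee_kj == pytest.approx(288.0 * 4.184, rel=1e-15)
        assert e.tee_kj_per_bw == pytest.approx(e.tee_kj / 9.7, rel=1e-15)
        assert e.tee_kj_per_mbw == pytest.approx(e.tee_kj / 9.7**0.75, rel=1e-15)

    def test_unit_mass_collapses_scales(self):
        e = dlw.scale_energy(123.0, 1.0)
        assert e.tee_per_bw == e.tee_per_mbw == e.tee_kcal


class TestFullChain:
    def test_fits_to_energy(self):
        """Forward-constructed fits run through the whole chain coherently."""
        dose = dlw.DoseRecord(dose_mass=20.9)
        n_d, n_o = 330.0, 316.0
        fit_d = dlw.KineticsFit("deuterium", k=0.08, n_points=2, r_squared=1.0,
                                intercept_excess=dose.ppm_mol_equivalent("deuterium") / n_d)
        fit_o = dlw.KineticsFit("oxygen18", k=0.1, n_points=2, r_squared=1.0,
                                intercept_excess=dose.ppm_mol_equivalent("oxygen18") / n_o)
        spaces, comp, energy = dlw.tee_from_fits(dose, fit_d, fit_o, fq=0.93, body_mass=9.7)
        assert spaces.N_D == pytest.approx(n_d)
        assert spaces.N_O == pytest.approx(n_o)
        expected_r = dlw.rco2(spaces.N_pooled, 0.08, 0.1)
        assert energy.rco2 == pytest.approx(expected_r)
        assert energy.tee_kcal == pytest.approx(dlw.weir_tee(expected_r, 0.93))
        assert comp.TBW == pytest.approx(0.01802 * spaces.N_pooled)
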