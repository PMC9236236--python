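"""Tests for intake accounting, apparent digestibility and ME intake."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zooenergetics import nutrition
from zooenergetics.nutrition import (
    DigestibilityCoefficients,
    FoodComposition,
    MacronutrientTotals,
    NutritionError,
    apparent_digestibility,
    consumed_mass,
    daily_intake_table,
    me_intake,
    tnc_by_difference,
)


class TestTncByDifference:
    def test_direct_subtraction_wild_diet_profile(self):
        assert tnc_by_difference(7, 11, 52, 3) == pytest.approx(27.0)

    def test_all_zero_components(self):
        assert tnc_by_difference(0, 0, 0, 0) == 100.0

    def test_oversum_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert tnc_by_difference(10, 20, 70, 3) == 0.0

    def test_out_of_range_component_rejected(self):
        with pytest.raises(NutritionError):
            tnc_by_difference(-1, 10, 10, 10)


class TestConsumedMass:
    def test_moisture_corrected_subtraction(self):
        # remaining 40 g weighed after losing 20% moisture -> 50 g as-offered
        assert consumed_mass(100.0, 40.0, moisture_loss=0.20) == pytest.approx(50.0)

    def test_nothing_remaining_means_all_consumed(self):
        assert consumed_mass(80.0, 0.0, moisture_loss=0.15) == 80.0

    def test_corrected_remainder_above_offer_clamps_to_zero(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert consumed_mass(100.0, 99.0, moisture_loss=0.20) == 0.0

    @given(
        offered=st.floats(0, 2000),
        frac_left=st.floats(0, 1),
        loss=st.floats(0, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_consumption_bounded_by_offer(self, offered, frac_left, loss):
        remaining = offered * frac_left * (1 - loss)
        c = consumed_mass(offered, remaining, moisture_loss=loss)
        assert 0.0 <= c <= offered + 1e-9


class TestDailyIntake:
    COMP = {
        "x": FoodComposition("x", "browse", dm_fraction=0.30,
                             ash_pct=5, cp_pct=20, ndf_pct=40, cf_pct=5),
        "y": FoodComposition("y", "fruit", dm_fraction=0.10,
                             ash_pct=4, cp_pct=5, ndf_pct=10, cf_pct=1),
    }

    def _log(self, rows):
        return pd.DataFrame(rows, columns=["animal_id", "date", "item_id", "offered_g", "remaining_g"])

    def test_single_item_single_product(self):
        log = self._log([("a", "2020-06-01", "x", 100.0, 0.0)])
        daily = daily_intake_table(log, self.COMP)
        row = daily.loc[("a", "2020-06-01")]
        assert row["dm_g"] == pytest.approx(30.0)
        assert row["cp_g"] == pytest.approx(6.0)
        assert row["tnc_g"] == pytest.approx(30.0 * 0.30)  # TNC = 30%

    def test_items_sum_additively(self):
        log2 = self._log([
            ("a", "2020-06-01", "x", 100.0, 0.0),
            ("a", "2020-06-01", "y", 200.0, 0.0),
        ])
        both = daily_intake_table(log2, self.COMP).loc[("a", "2020-06-01")]
        only_x = daily_intake_table(self._log([("a", "2020-06-01", "x", 100.0, 0.0)]), self.COMP)
        only_y = daily_intake_table(self._log([("a", "2020-06-01", "y", 200.0, 0.0)]), self.COMP)
        for col in ("dm_g", "cp_g", "ndf_g", "cf_g", "tnc_g"):
            assert both[col] == pytest.approx(
                only_x.iloc[0][col] + only_y.iloc[0][col]
            )

    def test_missing_composition_names_item(self):
        log = self._log([("a", "2020-06-01", "mystery", 10.0, 0.0)])
        with pytest.raises(NutritionError, match="mystery"):
            daily_intake_table(log, self.COMP)


class TestApparentDigestibility:
    def test_study_female_dry_matter(self, female_tables):
        intake, fecal = female_tables
        d = apparent_digestibility(intake, fecal)
        assert d.dm == pytest.approx((147.9 - 52.7) / 147.9 * 100, rel=1e-12)
        assert d.dm == pytest.approx(64.4, abs=0.05)

    def test_study_male_nonstructural_carbohydrate(self, male_tables):
        intake, fecal = male_tables
        d = apparent_digestibility(intake, fecal)
        assert d.tnc == pytest.approx(97.2, abs=0.05)

    def test_zero_fecal_output_gives_100(self):
        intake = MacronutrientTotals(100, 10, 20, 5, 30)
        none_out = MacronutrientTotals(0, 0, 0, 0, 0)
        d = apparent_digestibility(intake, none_out)
        assert all(v == 100.0 for v in d.as_dict().values())

    def test_zero_intake_flagged_undefined_not_zero(self):
        intake = MacronutrientTotals(100, 0, 20, 5, 30)
        fecal = MacronutrientTotals(30, 1, 5, 1, 2)
        d = apparent_digestibility(intake, fecal)
        assert d.cp is None
        assert any("cp" in f for f in d.flags)

    def test_fecal_above_intake_flagged_negative(self):
        intake = MacronutrientTotals(100, 10, 20, 5, 30)
        fecal = MacronutrientTotals(30, 12, 5, 1, 2)
        d = apparent_digestibility(intake, fecal)
        assert d.cp < 0
        assert any("exceeds intake" in f for f in d.flags)

    def test_monotone_in_fecal_output(self, female_tables):
        intake, fecal = female_tables
        d0 = apparent_digestibility(intake, fecal)
        more = MacronutrientTotals(fecal.dm_g, fecal.cp_g + 1.0, fecal.ndf_g,
                                   fecal.cf_g, fecal.tnc_g)
        d1 = apparent_digestibility(intake, more)
        assert d1.cp < d0.cp
        assert d1.ndf == d0.ndf


class TestMeIntake:
    DIG = DigestibilityCoefficients(dm=64.4, cp=50.8, ndf=52.0, cf=63.5, tnc=89.3)

    def test_single_nutrient_product(self):
        intake = MacronutrientTotals(100, 24.9, 0, 0, 0)
        dig = DigestibilityCoefficients(dm=None, cp=50.8, ndf=None, cf=None, tnc=None)
        me = me_intake(intake, dig)
        assert me.me_cp == pytest.approx(4 * 24.9 * 0.508)
        assert me.me_cp == pytest.approx(50.6, abs=0.01)

    def test_zero_digestibility_zero_me(self):
        intake = MacronutrientTotals(100, 10, 20, 5, 30)
        dig = DigestibilityCoefficients(dm=50, cp=0.0, ndf=50, cf=50, tnc=50)
        assert me_intake(intake, dig).me_cp == 0.0

    def test_study_female_total_is_fq_worked_input(self, female_tables):
        intake, _ = female_tables
        me = me_intake(intake, self.DIG)
        # brute-force sum of four products
        expected = (4 * 24.9 * 0.508 + 3 * 42.1 * 0.520
                    + 9 * 9.7 * 0.635 + 4 * 61.0 * 0.893)
        assert me.me_total == pytest.approx(expected, rel=1e-12)
        assert me.me_total == pytest.approx(390, abs=1)

    def test_conservation_total_equals_component_sum(self, female_tables):
        intake, _ = female_tables
        me = me_intake(intake, self.DIG)
        assert me.me_total == me.me_cp + me.me_ndf + me.me_cf + me.me_tnc


class TestPartition:
    COMP = {
        "b": FoodComposition("b", "browse", 0.3, 5, 10, 40, 3),
        "v": FoodComposition("v", "vegetable", 0.1, 5, 10, 10, 2),
    }
    DIG = DigestibilityCoefficients(dm=60, cp=50, ndf=50, cf=60, tnc=90)

    def _daily_me(self, rows):
        log = pd.DataFrame(rows, columns=["animal_id", "date", "item_id", "offered_g", "remaining_g"])
        return nutrition.daily_me_table(log, self.COMP, self.DIG)

    def test_all_browse_zero_nonbrowse(self):
        dme = self._daily_me([("a", "2020-06-01", "b", 100.0, 0.0)])
        browse, nonbrowse = nutrition.partition_me(dme)
        assert nonbrowse == 0.0
        assert browse > 0

    def test_partition_conserves_total(self):
        dme = self._daily_me([
            ("a", "2020-06-01", "b", 100.0, 10.0),
            ("a", "2020-06-01", "v", 50.0, 5.0),
            ("a", "2020-06-02", "b", 90.0, 0.0),
        ])
        assert (dme["browse_me"] + dme["nonbrowse_me"]).to_numpy() == pytest.approx(
            dme["me_total"].to_numpy()
        )
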