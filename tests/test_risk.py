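"""The dietary exposure cascade and the screening layers."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pterisk.core import Element
from pterisk.io import ExposureParams, LivestockLimits, ToxTable
from pterisk.risk import (
    FoodItem,
    assess,
    average_daily_dose,
    carcinogenic_risk,
    daily_intake_rate,
    hazard_index,
    hazard_quotient,
    livestock_screen,
    pmtdi_screen,
    total_cr,
)


@pytest.fixture
def exposure():
    return ExposureParams()


class TestDailyIntakeRate:
    def test_rice_grain_values(self):
        assert daily_intake_rate(5.2, 125.2, 70) == pytest.approx(9.301, abs=5e-4)
        assert daily_intake_rate(17.9, 125.2, 70) == pytest.approx(32.015, abs=5e-4)

    def test_zero_concentration(self):
        assert daily_intake_rate(0.0, 125.2, 70) == 0.0

    @given(c=st.floats(min_value=0, max_value=1e3))
    def test_unit_consistent_is_thousandth_of_published(self, c):
        pub = daily_intake_rate(c, 50.0, 70, "as_published")
        si = daily_intake_rate(c, 50.0, 70, "unit_consistent")
        assert si == pytest.approx(pub * 1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            daily_intake_rate(-1.0, 50.0, 70)


class TestAverageDailyDose:
    def test_noncarcinogenic_equals_dir_per_thousand(self, exposure):
        assert average_daily_dose(7.780, exposure, "non_carcinogenic") == pytest.approx(7.780e-3)

    def test_carcinogenic_scales_by_duration_over_lifetime(self, exposure):
        add = average_daily_dose(7.780, exposure, "carcinogenic")
        assert add == pytest.approx(7.780e-3 * 30 / 70)

    def test_zero_dir(self, exposure):
        assert average_daily_dose(0.0, exposure, "non_carcinogenic") == 0.0
        assert average_daily_dose(0.0, exposure, "carcinogenic") == 0.0

    @given(
        dir_value=st.floats(min_value=0, max_value=100),
        ef=st.floats(min_value=1, max_value=365),
        ed=st.floats(min_value=1, max_value=70),
        lifetime=st.floats(min_value=70, max_value=100),
    )
    def test_mode_ratio_is_duration_over_lifetime(self, dir_value, ef, ed, lifetime):
        params = ExposureParams(exposure_frequency=ef, exposure_duration=ed,
                                lifetime=lifetime)
        nc = average_daily_dose(dir_value, params, "non_carcinogenic")
        c = average_daily_dose(dir_value, params, "carcinogenic")
        assert c == pytest.approx(nc * ed / lifetime, rel=1e-9, abs=1e-300)


class TestHazardAndCancerRisk:
    def test_antimony_hazard_quotients(self):
        assert hazard_quotient(2.430e-3, 4.0e-4) == pytest.approx(6.075)
        assert hazard_quotient(0.731857e-3, 4.0e-4) == pytest.approx(1.830, abs=5e-4)

    def test_threshold_boundary(self):
        assert hazard_quotient(3e-4, 3e-4) == pytest.approx(1.0)

    def test_cr_chain_for_rice_copper(self, exposure):
        add_c = average_daily_dose(9.301, exposure, "carcinogenic")
        assert add_c == pytest.approx(3.986e-3, abs=2e-6)
        assert carcinogenic_risk(add_c, 1.7) == pytest.approx(6.776e-3, abs=5e-6)

    def test_cr_boundary_and_zero(self):
        assert carcinogenic_risk(0.0, 1.5) == 0.0
        assert carcinogenic_risk(1e-6, 1.0) == pytest.approx(1e-6)

    def test_sums_skip_absent_entries(self):
        assert hazard_index([1.0, None, 2.5]) == pytest.approx(3.5)
        assert total_cr([None, 2e-6]) == pytest.approx(2e-6)

    @given(c=st.floats(min_value=1e-6, max_value=1e3), scale=st.floats(min_value=0.1, max_value=10))
    def test_linearity_in_concentration(self, c, scale):
        exposure = ExposureParams()
        base = daily_intake_rate(c, 125.2, 70)
        scaled = daily_intake_rate(c * scale, 125.2, 70)
        assert scaled == pytest.approx(base * scale, rel=1e-9)
        hq0 = hazard_quotient(average_daily_dose(base, exposure, "non_carcinogenic"), 4e-4)
        hq1 = hazard_quotient(average_daily_dose(scaled, exposure, "non_carcinogenic"), 4e-4)
        assert hq1 == pytest.approx(hq0 * scale, rel=1e-9)


class TestAssess:
    def test_totals_dominate_components(self, exposure):
        foods = [
            FoodItem("rice", {Element.CU: 5.2, Element.AS: 0.15, Element.SB: 4.35}),
        ]
        res = assess(foods, exposure, ToxTable())
        grp = res.table[res.table["food"] == "rice"]
        hqt = float(res.aggregates["hqt"].iloc[0])
        crt = float(res.aggregates["crt"].iloc[0])
        assert hqt >= grp["hq"].max()
        assert crt >= grp["cr"].max()
        assert hqt == pytest.approx(grp["hq"].sum())
        assert crt == pytest.approx(grp["cr"].sum())

    def test_elements_without_rfd_or_sf_are_absent(self, exposure):
        foods = [FoodItem("corn", {Element.ZN: 10.0})]
        res = assess(foods, exposure, ToxTable())
        row = res.table.iloc[0]
        assert row["cr"] is None or row["cr"] != row["cr"]  # NaN/absent
        assert row["hq"] is not None

    def test_unmapped_food_label_is_an_error(self, exposure):
        foods = [FoodItem("durian", {Element.CU: 1.0})]
        with pytest.raises(KeyError, match="durian"):
            assess(foods, exposure, ToxTable())

    def test_diet_total_sums_over_foods(self, exposure):
        foods = [
            FoodItem("rice", {Element.CU: 5.2}),
            FoodItem("corn", {Element.CU: 4.25}),
        ]
        res = assess(foods, exposure, ToxTable())
        total = float(res.diet_total.loc[res.diet_total["element"] == "Cu", "dir"].iloc[0])
        assert total == pytest.approx(res.table["dir"].sum())


class TestScreens:
    def test_pmtdi_strict_exceedance(self):
        assert pmtdi_screen(9.301, 0.5)          # rice Cu far above PMTDI
        assert pmtdi_screen(0.030, 0.0021)       # cassava As: arithmetic flag
        assert not pmtdi_screen(0.5, 0.5)        # equality does not exceed

    def test_livestock_screen_flags_grass(self):
        table = livestock_screen(
            {"grass": {Element.CU: 18.3, Element.ZN: 27.3},
             "all_plants": {Element.CU: 16.9, Element.ZN: 31.1}},
        )
        assert table["exceeds"].all()
        at_limit = livestock_screen({"g": {Element.CU: 10.0, Element.ZN: 22.8}})
        assert not at_limit["exceeds"].any()

    def test_livestock_empty_group_absent(self):
        assert livestock_screen({"g": {}}).empty

    def test_limits_overridable_and_validated(self):
        table = livestock_screen({"g": {Element.CU: 18.3}},
                                 LivestockLimits(max_cu_feed=20.0))
        assert not table["exceeds"].any()
        with pytest.raises(ValueError):
            LivestockLimits(max_cu_feed=-1)
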