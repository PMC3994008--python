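"""Management schedules: treatment input rates, event audit, determinism."""

import pytest

from censoc.management import (
    TREATMENTS,
    ManagementEvent,
    annual_external_c_input,
    build_schedule,
    manure_timing,
    schedule_to_table,
    treatment_spec,
)
from censoc.sites import get_site

#: published annual organic-carbon inputs (kg C/ha/yr) during the experiment
EXPERIMENT_RATES = {
    ("changping", "NPKM"): 3150.0,
    ("changping", "hNPKM"): 4725.0,
    ("changping", "NPKS"): 1000.0,
    ("yangling", "NPKM"): 3327.0,
    ("yangling", "hNPKM"): 4990.5,  # 1.5 x 3327; table prints 4991
    ("yangling", "NPKS"): 1998.0,
    ("qiyang", "NPKM"): 5838.0,
    ("qiyang", "hNPKM"): 8757.0,
    ("qiyang", "NPKS"): 1052.0,
}


def _annual_organic_sum(events, year):
    return sum(e.amount for e in events if e.year == year and e.kind in ("manure", "straw"))


class TestTreatmentSpec:
    @pytest.mark.parametrize("site_name", ["changping", "yangling", "qiyang"])
    def test_hnpkm_is_one_and_a_half_times_npkm(self, site_name):
        site = get_site(site_name).config
        npkm = treatment_spec(site, "NPKM")
        hnpkm = treatment_spec(site, "hNPKM")
        assert hnpkm.manure_c == pytest.approx(1.5 * npkm.manure_c, abs=0.5)

    def test_unknown_code_lists_valid_ones(self, changping):
        with pytest.raises(ValueError, match="control"):
            treatment_spec(changping.config, "NPKX")

    def test_control_has_no_organic_inputs(self, yangling):
        spec = treatment_spec(yangling.config, "control")
        assert spec.manure_c == 0.0 and spec.straw_c == 0.0


class TestAnnualInput:
    @pytest.mark.parametrize("key,expected", sorted(EXPERIMENT_RATES.items()))
    def test_experiment_rates_match_published_table(self, key, expected):
        site_name, code = key
        site = get_site(site_name).config
        assert annual_external_c_input(site, code) == pytest.approx(expected, abs=0.5)

    @pytest.mark.parametrize("site_name", ["changping", "yangling", "qiyang"])
    def test_historical_manure_rate(self, site_name):
        site = get_site(site_name).config
        assert annual_external_c_input(site, "NPKM", "1901-1960") == 500.0
        assert annual_external_c_input(site, "control", "1961-1988") == 500.0
        assert annual_external_c_input(site, "NPKM", "1989") == 0.0

    def test_mineral_treatments_have_zero_organic_input(self, yangling):
        for code in ("control", "N", "NP", "NPK"):
            assert annual_external_c_input(yangling.config, code) == 0.0


class TestManureTiming:
    def test_qiyang_split(self, qiyang):
        assert manure_timing(qiyang.config) == [("pre-wheat", 0.30), ("pre-corn", 0.70)]

    def test_changping_single_application(self, changping):
        assert manure_timing(changping.config) == [("pre-wheat", 1.0)]

    @pytest.mark.parametrize("site_name", ["changping", "yangling", "qiyang"])
    def test_splits_sum_to_one(self, site_name):
        splits = manure_timing(get_site(site_name).config)
        assert sum(f for _, f in splits) == pytest.approx(1.0)


class TestBuildSchedule:
    @pytest.mark.parametrize("site_name", ["changping", "yangling", "qiyang"])
    @pytest.mark.parametrize("code", TREATMENTS)
    def test_annual_event_sums_reproduce_published_inputs(self, site_name, code):
        """Every experiment year's organic events sum to the published rate."""
        site = get_site(site_name).config
        events = build_schedule(site, code)
        expected = annual_external_c_input(site, code)
        for year in (1990, 2001, 2027, 2050):
            assert _annual_organic_sum(events, year) == pytest.approx(expected, abs=1e-9)
        for year in (1910, 1975):
            assert _annual_organic_sum(events, year) == pytest.approx(500.0)
        assert _annual_organic_sum(events, 1989) == 0.0

    def test_rotation_years_contain_both_crops(self, changping):
        events = build_schedule(changping.config, "NPK")
        y1975 = [e for e in events if e.year == 1975]
        crops = {e.crop for e in y1975 if e.kind == "plant"}
        assert crops == {"wheat", "corn"}

    def test_corn_monoculture_before_1961(self, changping):
        events = build_schedule(changping.config, "NPK")
        crops = {e.crop for e in events if e.year == 1930 and e.kind == "plant"}
        assert crops == {"corn"}

    def test_control_has_no_inputs_after_1989(self, qiyang):
        events = build_schedule(qiyang.config, "control")
        post = [e for e in events if e.year >= 1990 and e.kind in ("manure", "straw", "fertilize")]
        assert post == []

    def test_two_ploughings_per_cropping_year(self, yangling):
        events = build_schedule(yangling.config, "NPKM")
        for year in (1950, 1980, 1995, 2050):
            assert sum(1 for e in events if e.year == year and e.kind == "plough") == 2

    def test_events_are_date_ordered(self, changping):
        events = build_schedule(changping.config, "NPKS")
        keys = [(e.year, e.month) for e in events]
        assert keys == sorted(keys)

    def test_schedules_are_deterministic(self, qiyang):
        a = schedule_to_table(build_schedule(qiyang.config, "hNPKM"))
        b = schedule_to_table(build_schedule(qiyang.config, "hNPKM"))
        assert a.equals(b)


class TestEventValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ManagementEvent(2000, 5, "burn")

    def test_bad_month_rejected(self):
        with pytest.raises(ValueError, match="month"):
            ManagementEvent(2000, 13, "plough")
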