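"""Preprocessing: BED, schedule summaries, endpoints, exclusion cascade."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chronotox.preprocess import (
    ALPHA_BETA,
    RadiotherapyCourse,
    apply_exclusions,
    build_analysis_table,
    compute_bed,
    dichotomize_atrophy,
    dichotomize_erythema,
    schedule_summaries,
    summarize_schedule,
    time_distance,
)
from chronotox.solar import GeoSite, LocalTimestamp, local_to_solar


class TestBed:
    def test_standard_fractionation(self):
        course = RadiotherapyCourse(25, 2.0)
        assert compute_bed(course, 10.0) == pytest.approx(60.0)
        assert compute_bed(course, 3.0) == pytest.approx(50.0 * (1 + 2.0 / 3.0))

    def test_boost_is_additive(self):
        course = RadiotherapyCourse(25, 2.0, boost_n_fractions=8, boost_dose_per_fraction=2.0)
        assert compute_bed(course, 10.0) == pytest.approx(60.0 + 8 * 2.0 * 1.2)

    def test_boost_dose_defaults_to_main(self):
        a = RadiotherapyCourse(25, 2.0, boost_n_fractions=5)
        b = RadiotherapyCourse(25, 2.0, boost_n_fractions=5, boost_dose_per_fraction=2.0)
        assert compute_bed(a, 3.0) == compute_bed(b, 3.0)

    def test_hypofractionation_exceeds_at_equal_physical_dose(self):
        # same 50 Gy physical dose, larger fractions -> larger BED
        conv = compute_bed(RadiotherapyCourse(25, 2.0), 3.0)
        hypo = compute_bed(RadiotherapyCourse(20, 2.5), 3.0)
        assert hypo > conv

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            RadiotherapyCourse(0, 2.0)
        with pytest.raises(ValueError):
            RadiotherapyCourse(25, -1.0)
        with pytest.raises(ValueError):
            RadiotherapyCourse(25, 2.0, boost_n_fractions=-1)
        with pytest.raises(ValueError):
            compute_bed(RadiotherapyCourse(25, 2.0), 0.0)

    def test_endpoint_defaults(self):
        assert ALPHA_BETA == {"erythema": 10.0, "atrophy": 3.0}


class TestScheduleSummary:
    def test_mean_and_sample_sd(self):
        s = summarize_schedule([9.0, 10.0, 11.0])
        assert s.mean_solar_time == pytest.approx(10.0)
        assert s.sd_solar_time == pytest.approx(1.0)
        assert s.n_fractions_timed == 3

    def test_single_fraction_sd_zero(self):
        assert summarize_schedule([14.25]).sd_solar_time == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_schedule([])


class TestTimeDistance:
    def test_midnight_origin_is_identity(self):
        assert time_distance(9.75, 0.0) == pytest.approx(9.75)

    @given(st.floats(min_value=6.0, max_value=20.0), st.floats(min_value=0.0, max_value=4.0))
    def test_symmetric_about_origin(self, origin, h):
        assert time_distance(origin + h, origin) == pytest.approx(
            time_distance(origin - h, origin)
        )

    def test_vectorised(self):
        out = time_distance(np.array([14.5, 16.5]), 15.5)
        assert out == pytest.approx([1.0, 1.0])


class TestEndpoints:
    def test_erythema_rules(self):
        assert dichotomize_erythema(0, 2) == 1
        assert dichotomize_erythema(0, 3) == 1
        assert dichotomize_erythema(0, 1) == 0
        assert dichotomize_erythema(1, 3) == "excluded"
        assert dichotomize_erythema(None, 2) is None
        assert dichotomize_erythema(0, float("nan")) is None

    def test_atrophy_rules(self):
        assert dichotomize_atrophy(0, 1) == 1
        assert dichotomize_atrophy(1, 2) == 1
        assert dichotomize_atrophy(1, 1) == 0
        assert dichotomize_atrophy(2, 3) == "excluded"
        assert dichotomize_atrophy(0, None) is None

    def test_atrophy_sensitivity_excludes_any_baseline(self):
        assert dichotomize_atrophy(1, 2, sensitivity=True) == "excluded"
        assert dichotomize_atrophy(0, 1, sensitivity=True) == 1

    def test_rejects_non_integer_grades(self):
        with pytest.raises(ValueError):
            dichotomize_erythema(0.5, 2)
        with pytest.raises(ValueError):
            dichotomize_atrophy(0, 5)


def _cohort_frame():
    return pd.DataFrame(
        {
            "outcome": ["excluded", 1, 0, 1, np.nan, 0],
            "sd_solar_time": [3.0, 2.5, 1.0, 0.5, 0.5, 0.5],
            "bed": [60.0, 60.0, 60.0, np.nan, 60.0, 60.0],
            "mean_solar_time": [10.0] * 6,
        },
        index=pd.Index(range(6), name="patient_id"),
    )


class TestExclusions:
    def test_cascade_order_and_counts(self):
        # patient 0 fails both the baseline and the SD rule; it must be
        # counted once, under the first rule of the cascade
        table, report = apply_exclusions(_cohort_frame(), "atrophy")
        assert report == {"baseline": 1, "sd_gt_2h": 1, "incomplete": 2, "included": 2}
        assert sorted(table.index) == [2, 5]
        assert table["outcome"].tolist() == [0, 0]

    def test_idempotent(self):
        table, _ = apply_exclusions(_cohort_frame(), "atrophy")
        again, report = apply_exclusions(table, "atrophy")
        assert report["baseline"] == report["sd_gt_2h"] == report["incomplete"] == 0
        pd.testing.assert_frame_equal(again, table)

    def test_unknown_endpoint(self):
        with pytest.raises(ValueError):
            apply_exclusions(_cohort_frame(), "fibrosis")

    def test_everyone_excluded_raises(self):
        df = _cohort_frame().iloc[:1]
        with pytest.raises(RuntimeError):
            apply_exclusions(df, "atrophy")


class TestScheduleSummaries:
    def _fractions(self):
        dates = [dt.date(2016, 5, 2 + i) for i in range(5)]
        return pd.DataFrame(
            {
                "patient_id": ["p1"] * 5,
                "site_name": ["Milan"] * 5,
                "date": [d.isoformat() for d in dates],
                "local_time": [9.0, 9.5, 10.0, 10.5, 11.0],
            }
        ), dates

    def test_matches_scalar_conversion(self, sites):
        frac, dates = self._fractions()
        res = schedule_summaries(frac, sites)
        solar = [
            local_to_solar(LocalTimestamp(d, c, sites["Milan"]))
            for d, c in zip(dates, frac["local_time"])
        ]
        assert res.loc["p1", "mean_solar_time"] == pytest.approx(np.mean(solar), abs=1e-9)
        assert res.loc["p1", "sd_solar_time"] == pytest.approx(np.std(solar, ddof=1), abs=1e-9)
        assert res.loc["p1", "n_fractions_timed"] == 5
        assert res.loc["p1", "latitude"] == 45.5

    def test_parses_hhmm_strings(self, sites):
        frac, _ = self._fractions()
        frac["local_time"] = ["09:00", "09:30", "10:00", "10:30", "11:00"]
        res = schedule_summaries(frac, sites)
        ref = schedule_summaries(self._fractions()[0], sites)
        assert res.loc["p1", "mean_solar_time"] == pytest.approx(
            ref.loc["p1", "mean_solar_time"]
        )

    def test_explicit_utc_offset_column(self, sites):
        frac, _ = self._fractions()
        with_col = frac.assign(utc_offset=2.0)  # matches CEST in May
        a = schedule_summaries(frac, sites)
        b = schedule_summaries(with_col, sites)
        assert a.loc["p1", "mean_solar_time"] == pytest.approx(b.loc["p1", "mean_solar_time"])

    def test_unknown_site_raises(self, sites):
        frac, _ = self._fractions()
        frac.loc[0, "site_name"] = "Atlantis"
        with pytest.raises(KeyError):
            schedule_summaries(frac, sites)


class TestBuildAnalysisTable:
    def test_end_to_end_on_generated_cohort(self, small_cohort):
        table, report = build_analysis_table(
            small_cohort.patients, small_cohort.fractions, small_cohort.sites, "atrophy"
        )
        assert set(table["outcome"].unique()) <= {0, 1}
        for col in ("bed", "mean_solar_time", "sd_solar_time", "bmi", "surgery"):
            assert col in table.columns
            assert table[col].notna().all()
        assert (table["sd_solar_time"] <= 2.0).all()
        assert report["included"] + report["baseline"] + report["sd_gt_2h"] + report[
            "incomplete"
        ] == len(small_cohort.patients)
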