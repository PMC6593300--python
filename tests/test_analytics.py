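"""Utilization, spending and progression analytics on hand-counted
fixtures."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from ipp.admin_records import (
    DrugPrescription,
    ERAccess,
    HospitalDischarge,
    ObservationWindow,
    OutpatientRecord,
    RegisterRecord,
    SubjectRegistryRecord,
)
from ipp.analytics import (
    demand_breakdown,
    er_access_prevalence,
    home_care_rate,
    hospitalization_rates,
    progression_matrix,
    spending_by_level,
)

WINDOW = ObservationWindow(2013, 2014)


def _assignments(levels: dict[str, str]) -> pd.DataFrame:
    df = pd.DataFrame({"subject_id": list(levels), "level": list(levels.values())})
    return df.set_index("subject_id")


def _adm(sid, regime="ordinary", area="medical", atype="unplanned",
         year=2013, birth=False, cost=0.0):
    d = date(year, 5, 10)
    return HospitalDischarge(sid, d, d, regime, atype, area, ["8470"], birth, cost)


class TestHospitalizationRates:
    def test_hand_counted_rate(self):
        """200 same-stratum subjects, 24 hospitalized: 120.0 per 1,000."""
        ids = [f"s{i}" for i in range(200)]
        assignments = _assignments({s: "ChronicI" for s in ids})
        registry = [SubjectRegistryRecord(s, 1950, "F", "Area1") for s in ids]
        discharges = [_adm(s) for s in ids[:24]]
        out = hospitalization_rates(assignments, discharges, registry, WINDOW)
        (row,) = out.to_dict("records")
        assert row["rate_subjects"] == pytest.approx(120.0)
        assert row["population"] == 200

    def test_no_admissions_gives_zero_not_missing(self):
        assignments = _assignments({"a": "Healthy"})
        registry = [SubjectRegistryRecord("a", 1950, "F", "Area1")]
        out = hospitalization_rates(assignments, [], registry, WINDOW)
        assert out["rate_subjects"].tolist() == [0.0]

    def test_birth_and_daycase_admissions_do_not_qualify(self):
        assignments = _assignments({"a": "Healthy", "b": "Healthy"})
        registry = [SubjectRegistryRecord(s, 1950, "F", "Area1") for s in "ab"]
        discharges = [_adm("a", birth=True), _adm("b", regime="day_hospital")]
        out = hospitalization_rates(assignments, discharges, registry, WINDOW)
        assert out["subjects_hospitalized"].sum() == 0


class TestDemandBreakdown:
    def test_hand_counted_split(self):
        """10 admissions: 4 surgical (1 unplanned), 6 medical (3 unplanned)."""
        levels = {"a": "ChronicII"}
        discharges = (
            [_adm("a", area="surgical", atype="planned")] * 3
            + [_adm("a", area="surgical", atype="unplanned")]
            + [_adm("a", area="medical", atype="planned")] * 3
            + [_adm("a", area="medical", atype="unplanned")] * 3
        )
        out = demand_breakdown(_assignments(levels), discharges, WINDOW)
        row = out.loc["ChronicII"]
        assert row["pct_of_total_demand"] == pytest.approx(100.0)
        assert row["pct_surgical"] == pytest.approx(40.0)
        assert row["pct_surgical_unplanned"] == pytest.approx(25.0)
        assert row["pct_medical"] == pytest.approx(60.0)
        assert row["pct_medical_unplanned"] == pytest.approx(50.0)

    def test_all_surgical_reports_medical_as_missing(self):
        discharges = [_adm("a", area="surgical", atype="planned")]
        out = demand_breakdown(_assignments({"a": "Healthy"}), discharges, WINDOW)
        row = out.loc["Healthy"]
        assert row["pct_surgical"] == 100.0
        assert row["pct_surgical_unplanned"] == 0.0
        assert np.isnan(row["pct_medical_unplanned"])

    def test_demand_shares_close_to_100(self):
        discharges = [_adm("a"), _adm("b"), _adm("b", regime="day_surgery")]
        out = demand_breakdown(_assignments({"a": "Healthy", "b": "ChronicI"}),
                               discharges, WINDOW)
        assert out["pct_of_total_demand"].sum() == pytest.approx(100.0)
        assert out.loc["ChronicI", "n_admissions"] == 2  # day cases count


class TestERPrevalence:
    def test_hand_counted_prevalence(self):
        levels = {f"s{i}": "ChronicIII" for i in range(20)}
        er = [ERAccess(f"s{i}", date(2013, 2, 2)) for i in range(5)]
        out = er_access_prevalence(_assignments(levels), er, WINDOW)
        assert out["ChronicIII"] == pytest.approx(25.0)

    def test_no_events_is_zero_for_populated_levels(self):
        out = er_access_prevalence(_assignments({"a": "Healthy"}), [], WINDOW)
        assert out["Healthy"] == 0.0
        assert np.isnan(out["Terminal"])  # empty stratum reported missing


class TestHomeCare:
    def test_rate_by_level_and_area(self):
        levels = {"a": "ChronicIV", "b": "ChronicIV", "c": "Healthy"}
        registry = [SubjectRegistryRecord("a", 1940, "F", "Area1"),
                    SubjectRegistryRecord("b", 1940, "M", "Area1"),
                    SubjectRegistryRecord("c", 1980, "F", "Area2")]
        registers = [RegisterRecord("a", "home_care", 2013)]
        out = home_care_rate(_assignments(levels), registers, registry, WINDOW)
        row = out[(out["level"] == "ChronicIV") & (out["area"] == "Area1")].iloc[0]
        assert row["pct_in_home_care"] == pytest.approx(50.0)


class TestSpending:
    def test_mean_includes_zero_spenders_and_divides_by_years(self):
        levels = {"a": "ChronicI", "b": "ChronicI"}
        drugs = [DrugPrescription("a", date(2013, 1, 1), "C09AA05", 100.0)]
        out = spending_by_level(_assignments(levels), drugs, [], [], WINDOW)
        # 100 EUR over 2 subjects over 2 years
        assert out.loc["ChronicI", "mean_drugs"] == pytest.approx(25.0)

    def test_five_subject_hand_fixture(self):
        levels = {s: "ChronicII" for s in "abcde"}
        drugs = [DrugPrescription(s, date(2014, 3, 1), "A10BA02", c)
                 for s, c in zip("abc", (40.0, 60.0, 100.0))]
        visits = [OutpatientRecord("d", date(2013, 7, 1), "diabetology", 30.0)]
        hosp = [_adm("e", cost=500.0)]
        out = spending_by_level(_assignments(levels), drugs, visits, hosp, WINDOW)
        row = out.loc["ChronicII"]
        assert row["mean_drugs"] == pytest.approx(20.0)        # 200 / 5 / 2
        assert row["mean_outpatient"] == pytest.approx(3.0)    # 30 / 5 / 2
        assert row["mean_hospitalization"] == pytest.approx(50.0)


class TestProgression:
    def test_identity_progression_is_diagonal(self):
        levels = {"a": "Healthy", "b": "ChronicI", "c": "ChronicIV"}
        y1 = _assignments(levels)
        result = progression_matrix(y1, y1.copy())
        for lv in levels.values():
            assert result.matrix.loc[lv, lv] == pytest.approx(100.0)

    def test_hand_counted_transition_row(self):
        y1 = _assignments({s: "ChronicI" for s in "abcd"})
        y2 = _assignments({"a": "ChronicI", "b": "ChronicI", "c": "ChronicI",
                           "d": "ChronicII"})
        result = progression_matrix(y1, y2)
        assert result.matrix.loc["ChronicI", "ChronicI"] == pytest.approx(75.0)
        assert result.matrix.loc["ChronicI", "ChronicII"] == pytest.approx(25.0)

    def test_rows_sum_to_100_and_deaths_excluded(self):
        y1 = _assignments({"a": "ChronicI", "b": "Terminal", "c": "EarlySymptoms"})
        y2 = _assignments({"a": "ChronicII", "c": "ChronicI", "d": "Healthy"})
        result = progression_matrix(y1, y2, deaths_in_y1={"b"})
        sums = result.matrix.sum(axis=1)
        occupied = sums[sums > 0]
        assert np.allclose(occupied, 100.0)
        assert result.excluded_deaths == ["b"]
        assert result.entrants == ["d"]
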