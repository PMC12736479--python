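from __future__ import annotations

from datetime import date

import pytest

from pimscreen import (
    DeathRecord,
    build_cohort,
    chronic_in_year,
    co_dispensed,
    detect_all,
    duration_over_8_weeks,
    evaluate_rule,
    parse_route_form,
    parse_strength,
    unit_dose_exceeds,
)
from pimscreen.catalog import PIMRule
from pimscreen.engine import MissingUnitDose

from conftest import make_record


class TestDurationOver8Weeks:
    def test_gap_inside_band_qualifies(self):
        hit, pairs = duration_over_8_weeks([date(2019, 1, 1), date(2019, 3, 15)])
        assert hit and pairs == [(date(2019, 1, 1), date(2019, 3, 15))]

    def test_single_date_never_qualifies(self):
        assert duration_over_8_weeks([date(2019, 1, 1)]) == (False, [])

    def test_gaps_outside_band_rejected(self):
        # consecutive gaps 29 and 305 days: neither in (56, 180]
        hit, pairs = duration_over_8_weeks(
            [date(2019, 1, 1), date(2019, 1, 30), date(2019, 12, 1)]
        )
        assert not hit and pairs == []

    @pytest.mark.parametrize(
        "gap, expected", [(56, False), (57, True), (180, True), (181, False)]
    )
    def test_strict_lower_inclusive_upper_bounds(self, gap, expected):
        from datetime import timedelta

        d0 = date(2019, 1, 1)
        hit, _ = duration_over_8_weeks([d0, d0 + timedelta(days=gap)])
        assert hit is expected

    def test_pairwise_on_consecutive_dates_only(self):
        # 1 Jan -> 1 Mar is 59 days via a middle date; consecutive gaps are
        # 30 and 29 days, so the literal consecutive-pair screen stays quiet
        hit, _ = duration_over_8_weeks(
            [date(2019, 1, 1), date(2019, 1, 31), date(2019, 3, 1)]
        )
        assert not hit


class TestCoDispensed:
    def test_within_window(self):
        assert co_dispensed([date(2019, 1, 1)], [date(2019, 2, 15)])

    def test_beyond_window(self):
        assert not co_dispensed([date(2019, 1, 1)], [date(2019, 6, 1)])

    def test_any_pair_suffices(self):
        assert co_dispensed(
            [date(2019, 1, 1), date(2019, 7, 1)], [date(2019, 7, 10)]
        )

    def test_symmetric_and_boundary_inclusive(self):
        from datetime import timedelta

        a, b = [date(2019, 5, 1)], [date(2019, 5, 1) + timedelta(days=90)]
        assert co_dispensed(a, b) and co_dispensed(b, a)
        assert not co_dispensed(a, [b[0] + timedelta(days=1)])


class TestChronicInYear:
    def test_five_events_chronic(self):
        dates = [date(2021, m, 1) for m in range(1, 6)]
        assert chronic_in_year(dates, 2021)

    def test_four_events_not_chronic(self):
        assert not chronic_in_year([date(2021, m, 1) for m in range(1, 5)], 2021)

    def test_counts_are_per_calendar_year(self):
        dates = [date(2020, m, 1) for m in (10, 11, 12)] + [
            date(2021, m, 1) for m in (1, 2, 3)
        ]
        assert not chronic_in_year(dates, 2020)
        assert not chronic_in_year(dates, 2021)

    def test_same_day_duplicates_collapse(self):
        dates = [date(2021, 1, 1)] * 6
        assert not chronic_in_year(dates, 2021)


class TestUnitDose:
    def test_explicit_dose_over_threshold(self):
        rec = make_record(atc_code="B01AC06", unit_dose_mg=500.0)
        assert unit_dose_exceeds(rec, 325)

    def test_equal_dose_not_over(self):
        rec = make_record(atc_code="B01AC06", unit_dose_mg=325.0)
        assert not unit_dose_exceeds(rec, 325)

    def test_missing_dose_raises_flagged_error(self):
        rec = make_record(medication_name="ASPIRIN CPR", unit_dose_mg=None)
        with pytest.raises(MissingUnitDose):
            unit_dose_exceeds(rec, 325)

    def test_dose_parsed_from_name_when_column_absent(self):
        rec = make_record(medication_name="ASA 500MG TABS", unit_dose_mg=None)
        assert unit_dose_exceeds(rec, 325)


class TestNameParsing:
    @pytest.mark.parametrize(
        "name, mg",
        [
            ("ASA 500MG TABS", 500.0),
            ("METFORMIN 1G", 1000.0),
            ("INSULIN 100IU/ML", None),
            ("DIGOXIN 0.25 MG CPR", 0.25),
            ("AMOXICILLIN 1,5G FL", 1500.0),
        ],
    )
    def test_parse_strength(self, name, mg):
        assert parse_strength(name) == mg

    @pytest.mark.parametrize(
        "name, route, form",
        [
            ("PANTOPRAZOLE 40MG TABS", "ORAL", "TABLET"),
            ("DICLOFENAC CREAM 1%", "TOPICAL", "CREAM"),
            ("XYZ 10", "UNKNOWN", "UNKNOWN"),
            ("KETOPROFENE 100MG SUPP", "RECTAL", "SUPPOSITORY"),
            ("FENTANYL 25MCG CEROTTO", "TRANSDERMAL", "PATCH"),
            ("CEFTRIAXONE 1G FL", "PARENTERAL", "SOLUTION"),
            ("paracetamolo 500mg cpr", "ORAL", "TABLET"),
        ],
    )
    def test_parse_route_form(self, name, route, form):
        rf = parse_route_form(name)
        assert (rf.route, rf.form) == (route, form)


class TestEvaluateRule:
    def test_always_rule_single_dispensation(self, catalog):
        rule = next(r for r in catalog.rules if r.rule_id == "paroxetine")
        history = [
            make_record(atc_code="N06AB05", dispense_date=date(2020, 4, 1),
                        medication_name="PAROXETINE 20MG CPR")
        ]
        ev = evaluate_rule(history, rule, 2020, catalog)
        assert ev is not None and ev.category == "AVOID" and ev.year == 2020
        assert evaluate_rule(history, rule, 2019, catalog) is None

    def test_ppi_two_dispensations_in_band(self, catalog):
        rule = next(r for r in catalog.rules if r.rule_id == "ppi_long_term")
        history = [
            make_record(dispense_date=date(2020, 1, 1)),
            make_record(dispense_date=date(2020, 3, 15)),
        ]
        ev = evaluate_rule(history, rule, 2020, catalog)
        assert ev is not None and ev.n_triggers == 2

    def test_ppi_single_dispensation_no_event(self, catalog):
        rule = next(r for r in catalog.rules if r.rule_id == "ppi_long_term")
        history = [make_record(dispense_date=date(2020, 1, 1))]
        assert evaluate_rule(history, rule, 2020, catalog) is None

    def test_duration_event_attributed_to_later_date_year(self, catalog):
        rule = next(r for r in catalog.rules if r.rule_id == "ppi_long_term")
        history = [
            make_record(dispense_date=date(2019, 12, 1)),
            make_record(dispense_date=date(2020, 2, 15)),  # gap 76 days
        ]
        assert evaluate_rule(history, rule, 2019, catalog) is None
        assert evaluate_rule(history, rule, 2020, catalog) is not None

    def test_co_dispensing_attributed_to_index_year(self, catalog):
        rule = next(r for r in catalog.rules if r.rule_id == "nsaid_corticosteroid")
        history = [
            make_record(atc_code="M01AB05", dispense_date=date(2020, 12, 20),
                        medication_name="DICLOFENAC 50MG CPR"),
            make_record(atc_code="H02AB07", dispense_date=date(2021, 1, 10),
                        medication_name="PREDNISONE 25MG CPR"),
        ]
        assert evaluate_rule(history, rule, 2020, catalog) is not None
        assert evaluate_rule(history, rule, 2021, catalog) is None


class TestDetectAll:
    def test_empty_cohort_empty_events(self, catalog, window):
        cohort = build_cohort([], [], window)
        assert detect_all(cohort, [], catalog) == []

    def test_ticlopidine_six_dispensations_one_event(self, catalog, window):
        records = [
            make_record(
                atc_code="B01AC05",
                medication_name="TICLOPIDINE 250MG CPR",
                dispense_date=date(2019, m, 5),
            )
            for m in range(1, 7)
        ]
        cohort = build_cohort(records, [], window)
        events = detect_all(cohort, records, catalog)
        assert len(events) == 1
        ev = events[0]
        assert (ev.rule_id, ev.category, ev.year, ev.n_triggers) == (
            "ticlopidine",
            "AVOID",
            2019,
            6,
        )

    def test_one_event_per_patient_rule_year(self, catalog, window):
        records = [
            make_record(
                atc_code="N06AB05",
                medication_name="PAROXETINE 20MG CPR",
                dispense_date=date(2020, m, 1),
            )
            for m in (1, 6, 11)
        ]
        cohort = build_cohort(records, [], window)
        events = detect_all(cohort, records, catalog)
        keys = [(e.patient_id, e.rule_id, e.year) for e in events]
        assert len(keys) == len(set(keys))
        # paroxetine fires both its AVOID rule and its anticholinergic rule
        assert {e.rule_id for e in events} == {"paroxetine", "achol_paroxetine"}

    def test_non_cohort_patient_ignored(self, catalog, window):
        records = [
            make_record(
                birth_date=date(1958, 6, 1),  # 63 at window end
                atc_code="B01AC05",
                medication_name="TICLOPIDINE 250MG CPR",
            )
        ]
        cohort = build_cohort(records, [], window)
        assert detect_all(cohort, records, catalog) == []

    def test_deceased_patient_produces_no_events(self, catalog, window):
        records = [make_record(atc_code="N06AB05")]
        deaths = [DeathRecord("P001", date(2021, 6, 1))]
        cohort = build_cohort(records, deaths, window)
        assert detect_all(cohort, records, catalog) == []

    def test_output_order_deterministic(self, catalog, window):
        records = [
            make_record(patient_id="PB", atc_code="N06AB05",
                        dispense_date=date(2019, 2, 1)),
            make_record(patient_id="PA", atc_code="B01AC05",
                        dispense_date=date(2020, 2, 1)),
            make_record(patient_id="PA", atc_code="N06AB05",
                        dispense_date=date(2019, 2, 1)),
        ]
        cohort = build_cohort(records, [], window)
        events = detect_all(cohort, records, catalog)
        keys = [(e.patient_id, e.year, e.rule_id) for e in events]
        assert keys == sorted(keys)
        assert events == detect_all(cohort, list(reversed(records)), catalog)
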