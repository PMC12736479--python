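from __future__ import annotations

from datetime import date

import pytest

from pimscreen import (
    annual_prevalence,
    build_cohort,
    detect_all,
    group_atc_level4,
    percent,
    rank_pims,
    summarize_sample,
)
from pimscreen.engine import PIMEvent

from conftest import make_record


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (65807, 115962, 56.7),
            (0, 10, 0.0),
            (1738, 2368, 73.4),
            (1, 8, 12.5),
            (10, 10, 100.0),
        ],
    )
    def test_half_up_rounding(self, num, den, expected):
        assert percent(num, den) == expected

    def test_half_up_not_bankers(self):
        # 0.05% rounds up to 0.1, where banker's rounding would give 0.0
        assert percent(1, 2000) == 0.1
        assert percent(25, 1000, decimals=1) == 2.5
        assert percent(25, 1000, decimals=0) == 3.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(0, 0)

    def test_numerator_above_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(3, 2)


def _event(pid, year, rule_id="paroxetine", category="AVOID", label="Paroxetine"):
    trig = make_record(
        patient_id=pid,
        atc_code="N06AB05",
        dispense_date=date(year, 3, 1),
        medication_name="PAROXETINE 20MG CPR",
    )
    return PIMEvent(pid, rule_id, category, label, year, (trig,))


class TestAnnualPrevalence:
    def _cohort(self, window, pids_by_year):
        records = []
        for year, pids in pids_by_year.items():
            for pid in pids:
                records.append(
                    make_record(
                        patient_id=pid,
                        birth_date=date(1940, 1, 1),
                        dispense_date=date(year, 6, 1),
                    )
                )
        return build_cohort(records, [], window)

    def test_no_events_all_zero(self, window):
        cohort = self._cohort(window, {2019: ["A", "B"]})
        cells = annual_prevalence([], cohort)
        assert all(c.percent == 0.0 for c in cells)

    def test_single_year_hit(self, window):
        cohort = self._cohort(window, {y: ["A", "B", "C", "D"] for y in window.years})
        cells = annual_prevalence([_event("A", 2019)], cohort)
        by_year = {c.year: c for c in cells}
        assert by_year[2019].percent == 25.0
        assert by_year[2020].percent == 0.0
        assert by_year["total"].numerator == 1
        assert by_year["total"].denominator == 4

    def test_category_filter(self, window):
        cohort = self._cohort(window, {2019: ["A", "B"]})
        events = [
            _event("A", 2019),
            _event("B", 2019, "furosemide", "CAUTION", "Furosemide"),
        ]
        avoid = {c.year: c for c in annual_prevalence(events, cohort, "AVOID")}
        assert avoid[2019].numerator == 1

    def test_numerators_bounded_by_denominators(self, window):
        cohort = self._cohort(window, {y: ["A", "B"] for y in window.years})
        events = [_event("A", y) for y in window.years]
        for c in annual_prevalence(events, cohort):
            assert 0 <= c.numerator <= c.denominator
            assert 0.0 <= c.percent <= 100.0


class TestRankPims:
    def test_single_group_ranks_first_at_100(self):
        events = [_event("A", 2020, "ppi_long_term", "AVOID", "PPI")]
        rows = rank_pims(events, 2020, "AVOID")
        assert len(rows) == 1
        assert (rows[0].rank, rows[0].label, rows[0].percent) == (1, "PPI", 100.0)

    def test_counts_and_ordering(self):
        events = []
        for i in range(87):
            events.append(_event(f"ppi{i}", 2020, "ppi_long_term", "AVOID", "PPI"))
        for i in range(8):
            events.append(_event(f"par{i}", 2020))
        for i in range(5):
            events.append(_event(f"su{i}", 2020, "sulfonylureas", "AVOID", "SU"))
        rows = rank_pims(events, 2020, "AVOID")
        assert [(r.rank, r.label, r.percent) for r in rows] == [
            (1, "PPI", 87.0),
            (2, "Paroxetine", 8.0),
            (3, "SU", 5.0),
        ]

    def test_tie_broken_by_label(self):
        events = [
            _event("a1", 2020, "r_b", "AVOID", "Bravo"),
            _event("a2", 2020, "r_b", "AVOID", "Bravo"),
            _event("a1", 2020, "r_a", "AVOID", "Alpha"),
            _event("a2", 2020, "r_a", "AVOID", "Alpha"),
        ]
        rows = rank_pims(events, 2020, "AVOID")
        assert [r.label for r in rows] == ["Alpha", "Bravo"]

    def test_top_k_and_threshold(self):
        events = [_event(f"p{i}", 2020, "ppi_long_term", "AVOID", "PPI") for i in range(99)]
        events.append(_event("q", 2020, "amiodarone", "AVOID", "Amiodarone"))
        rows = rank_pims(events, 2020, "AVOID", top_k=6, min_percent=2.0)
        assert [r.label for r in rows] == ["PPI"]  # amiodarone at 1.0% drops

    def test_empty_year_empty_table(self):
        assert rank_pims([], 2020, "AVOID") == []


class TestGrouping:
    @pytest.mark.parametrize(
        "code, prefix",
        [("C03CA01", "C03CA"), ("A02BC02", "A02BC"), ("N06AB05", "N06AB")],
    )
    def test_level4_prefix(self, code, prefix):
        assert group_atc_level4(code) == prefix

    def test_short_code_returned_unchanged(self):
        assert group_atc_level4("A02BC") == "A02BC"


class TestSummarizeSample:
    def test_median_iqr_by_interpolation(self, window):
        records = [
            make_record(
                patient_id=p,
                birth_date=date(2021 - age, 1, 1),
                atc_code="N06AB05",
                medication_name="PAROXETINE 20MG CPR",
                dispense_date=date(2019, 6, 1),
            )
            for p, age in [("A", 70), ("B", 76), ("C", 82)]
        ]
        cohort = build_cohort(records, [], window)
        events = [_event(p, 2019) for p in ("A", "B", "C")]
        s = summarize_sample(cohort, events)
        assert s["n_patients"] == 3
        assert s["age_median"] == 76.0
        assert s["age_iqr"] == (73.0, 79.0)

    def test_single_patient_degenerate_quartiles(self, window):
        records = [
            make_record(
                birth_date=date(1950, 1, 1),
                atc_code="N06AB05",
                dispense_date=date(2019, 6, 1),
            )
        ]
        cohort = build_cohort(records, [], window)
        s = summarize_sample(cohort, [_event("P001", 2019)])
        assert s["age_median"] == s["age_iqr"][0] == s["age_iqr"][1]

    def test_category_counts_and_male_share(self, window):
        records = [
            make_record(patient_id="A", sex="M", birth_date=date(1940, 1, 1),
                        dispense_date=date(2019, 6, 1)),
            make_record(patient_id="B", sex="F", birth_date=date(1940, 1, 1),
                        dispense_date=date(2019, 6, 1)),
        ]
        cohort = build_cohort(records, [], window)
        events = [
            _event("A", 2019),
            _event("B", 2019, "furosemide", "CAUTION", "Furosemide"),
        ]
        s = summarize_sample(cohort, events)
        assert s["males_n"] == 1 and s["males_percent"] == 50.0
        assert s["avoid_n"] == 1 and s["caution_n"] == 1

    def test_end_to_end_with_detector(self, catalog, window):
        records = []
        for m in (1, 4, 7):
            records.append(
                make_record(
                    atc_code="N06AB05",
                    medication_name="PAROXETINE 20MG CPR",
                    dispense_date=date(2020, m, 1),
                )
            )
        cohort = build_cohort(records, [], window)
        events = detect_all(cohort, records, catalog)
        s = summarize_sample(cohort, events, year=2020)
        # 3 trigger dispensations shared by two paroxetine rules count once
        assert s["pims_per_patient_median"] == 3.0
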