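import datetime as dt

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedpv import preprocess as pp
from pedpv.preprocess import AgeGroup

from conftest import make_case


class TestComputeAgeDays:
    def test_same_day_is_zero(self):
        d = dt.date(2010, 3, 15)
        assert pp.compute_age_days(d, d) == 0

    def test_leap_year_span_is_366_days(self):
        # 2008 is a leap year: one full year from 2008-01-01 crosses Feb 29
        assert pp.compute_age_days(dt.date(2008, 1, 1), dt.date(2009, 1, 1)) == 366

    def test_reversed_dates_raise_with_case_context(self):
        with pytest.raises(pp.NegativeAgeError, match="C42"):
            pp.compute_age_days(dt.date(2010, 3, 15), dt.date(2010, 3, 14), "C42")


class TestClassifyAgeGroup:
    def test_180_days_is_baby(self):
        assert pp.classify_age_group(pp.years_from_age_days(180)) == AgeGroup.BABY

    def test_first_birthday_is_toddler(self):
        years = pp.completed_years(dt.date(2010, 4, 1), dt.date(2011, 4, 1))
        assert years == 1
        assert pp.classify_age_group(years) == AgeGroup.TODDLER

    @pytest.mark.parametrize(
        "years,group",
        [
            (0, AgeGroup.BABY),
            (1, AgeGroup.TODDLER),
            (2, AgeGroup.TODDLER),
            (3, AgeGroup.PRESCHOOL),
            (4, AgeGroup.PRESCHOOL),
            (5, AgeGroup.PRIMARY_SCHOOL),
            (7, AgeGroup.PRIMARY_SCHOOL),
            (8, AgeGroup.SECONDARY_SCHOOL),
            (11, AgeGroup.SECONDARY_SCHOOL),
        ],
    )
    def test_half_open_partition(self, years, group):
        assert pp.classify_age_group(years) == group

    def test_12th_birthday_included_but_not_beyond(self):
        assert pp.classify_age_group(12, on_12th_birthday=True) == AgeGroup.SECONDARY_SCHOOL
        with pytest.raises(pp.AgeOutOfRangeError):
            pp.classify_age_group(12)
        with pytest.raises(pp.AgeOutOfRangeError):
            pp.classify_age_group(13)

    def test_negative_age_rejected(self):
        with pytest.raises(pp.AgeOutOfRangeError):
            pp.classify_age_group(-1)

    @given(st.dates(dt.date(1996, 1, 1), dt.date(2001, 12, 31)), st.integers(0, 4382))
    def test_every_in_window_age_maps_to_exactly_one_group(self, birth, offset):
        event = birth + dt.timedelta(days=offset)
        try:
            years = pp.completed_years(birth, event)
            group = pp.classify_age_group(
                years,
                on_12th_birthday=(event.month, event.day) == (birth.month, birth.day),
            )
        except pp.AgeOutOfRangeError:
            assert pp.completed_years(birth, event) >= 12
            return
        assert isinstance(group, AgeGroup)


def test_dates_win_over_explicit_age_days(caplog):
    case = make_case(
        "C1", ["D"], ["E"],
        birth_date=dt.date(2005, 1, 1), event_date=dt.date(2010, 1, 1),
        age_days=100,  # disagrees: dates say 5 years
    )
    import logging

    with caplog.at_level(logging.WARNING):
        group = pp.age_group_of(case)
    assert group == AgeGroup.PRIMARY_SCHOOL
    assert any("disagrees" in r.message for r in caplog.records)


def test_filter_serious_counts():
    cases = [
        make_case(f"C{i}", ["D"], ["E"], seriousness=s)
        for i, s in enumerate(
            ["death", "not_serious", "medically_important", "not_serious", "life_threatening"]
        )
    ]
    kept = pp.filter_serious(cases)
    assert [c.case_id for c in kept] == ["C0", "C2", "C4"]
    assert pp.filter_serious([cases[1], cases[3]]) == []


def test_preprocess_excludes_out_of_window_and_not_serious():
    cases = [
        make_case("IN", ["D"], ["E"], age_days=500),
        make_case("OLD", ["D"], ["E"], age_days=6000),
        make_case("NS", ["D"], ["E"], age_days=500, seriousness="not_serious"),
        make_case(
            "NEG", ["D"], ["E"],
            birth_date=dt.date(2010, 5, 1), event_date=dt.date(2010, 4, 1),
        ),
    ]
    serious, exclusions = pp.preprocess_reports(cases)
    assert [c.case_id for c in serious] == ["IN"]
    assert dict(exclusions) == {
        "OLD": "age outside 0-12-year window",
        "NS": "not serious",
        "NEG": "event_date precedes birth_date",
    }


def test_partition_counts_sum_to_total():
    import numpy as np

    from pedpv import synthetic_data as sd

    cfg = sd.default_notivisa_like_config(seed=11)
    cfg.n_reports = 400
    reports, _ = sd.generate_database(cfg)
    groups = [pp.age_group_of(r) for r in reports]
    counts = {g: groups.count(g) for g in AgeGroup}
    assert sum(counts.values()) == len(reports)
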