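"""Age derivation, pediatric age-group classification, and seriousness filtering.

The study population is children from birth to the 12th birthday inclusive.
Age in completed years is anniversary-based: a child is *n* years old from
the *n*-th birthday up to the day before the *(n+1)*-th. Pediatric
development stages partition that window as half-open-left intervals, with
the last group closed at the 12th birthday:

=================  ====================
baby               [0, 1) years
toddler            [1, 3) years
preschool          [3, 5) years
primary_school     [5, 8) years
secondary_school   [8, 12] years (12 only on the birthday itself)
=================  ====================
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .icsr_model import CaseReport

logger = logging.getLogger(__name__)


class AgeGroup(str, enum.Enum):
    BABY = "baby"
    TODDLER = "toddler"
    PRESCHOOL = "preschool"
    PRIMARY_SCHOOL = "primary_school"
    SECONDARY_SCHOOL = "secondary_school"


#: Lower bound of each group in completed years (upper bound = next lower).
_GROUP_LOWER_YEARS: list[tuple[AgeGroup, int]] = [
    (AgeGroup.BABY, 0),
    (AgeGroup.TODDLER, 1),
    (AgeGroup.PRESCHOOL, 3),
    (AgeGroup.PRIMARY_SCHOOL, 5),
    (AgeGroup.SECONDARY_SCHOOL, 8),
]

MAX_COMPLETED_YEARS = 11  # 12 is in-window only on the 12th birthday itself
MEAN_DAYS_PER_YEAR = 365.2425  # Gregorian mean, used when only age_days is known


class NegativeAgeError(ValueError):
    """The event date precedes the birth date."""

    def __init__(self, birth_date: dt.date, event_date: dt.date, case_id: str = "?"):
        self.case_id = case_id
        super().__init__(
            f"case {case_id}: event date {event_date} precedes birth date {birth_date}"
        )


class AgeOutOfRangeError(ValueError):
    """Age falls outside the 0–12-year pediatric inclusion window."""


def compute_age_days(
    birth_date: dt.date, event_date: dt.date, case_id: str = "?"
) -> int:
    """Exact calendar-day difference between event onset and birth."""
    delta = (event_date - birth_date).days
    if delta < 0:
        raise NegativeAgeError(birth_date, event_date, case_id)
    return delta


def completed_years(birth_date: dt.date, event_date: dt.date) -> int:
    """Anniversary-based age in completed years.

    A 29-February birthday is treated as completed on 1 March of common
    years (the (month, day) pair comparison below).
    """
    if event_date < birth_date:
        raise NegativeAgeError(birth_date, event_date)
    years = event_date.year - birth_date.year
    if (event_date.month, event_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def years_from_age_days(age_days: int) -> int:
    """Completed years estimated from an age in days (no dates available)."""
    if age_days < 0:
        raise AgeOutOfRangeError(f"negative age in days: {age_days}")
    return int(age_days // MEAN_DAYS_PER_YEAR)


def classify_age_group(
    years: int, *, on_12th_birthday: bool = False
) -> AgeGroup:
    """Map completed years to the pediatric development stage.

    ``years=12`` is accepted only when ``on_12th_birthday`` is true (the
    inclusion window closes at the 12th birthday, not the 13th).
    """
    if years < 0:
        raise AgeOutOfRangeError(f"negative age: {years} years")
    if years == 12 and on_12th_birthday:
        return AgeGroup.SECONDARY_SCHOOL
    if years > MAX_COMPLETED_YEARS:
        raise AgeOutOfRangeError(
            f"age {years} completed years exceeds the 0-12-year study window"
        )
    group = _GROUP_LOWER_YEARS[0][0]
    for candidate, lower in _GROUP_LOWER_YEARS:
        if years >= lower:
            group = candidate
    return group


def age_group_of(report: CaseReport) -> AgeGroup:
    """Age group for a case, preferring the date pair over age_days.

    When both an explicit ``age_days`` and a complete date pair are present
    and disagree, the date-derived value wins and the discrepancy is logged.
    """
    if report.birth_date is not None and report.event_date is not None:
        days = compute_age_days(report.birth_date, report.event_date, report.case_id)
        if report.age_days is not None and report.age_days != days:
            logger.warning(
                "case %s: age_days=%d disagrees with date-derived %d; using dates",
                report.case_id,
                report.age_days,
                days,
            )
        years = completed_years(report.birth_date, report.event_date)
        anniversary = (
            report.event_date.month == report.birth_date.month
            and report.event_date.day == report.birth_date.day
        )
        return classify_age_group(years, on_12th_birthday=anniversary and years == 12)
    if report.age_days is None:
        raise AgeOutOfRangeError(f"case {report.case_id}: no age information")
    return classify_age_group(years_from_age_days(report.age_days))


def derive_ages(
    reports: Iterable[CaseReport],
) -> tuple[list[CaseReport], list[tuple[str, str]]]:
    """Fill ``age_days`` from dates and drop cases outside the 0-12-y window.

    Returns the retained cases (order preserved, ``age_days`` populated) and
    an exclusion log of ``(case_id, reason)`` pairs.
    """
    retained: list[CaseReport] = []
    exclusions: list[tuple[str, str]] = []
    for report in reports:
        try:
            if report.birth_date is not None and report.event_date is not None:
                report.age_days = compute_age_days(
                    report.birth_date, report.event_date, report.case_id
                )
            age_group_of(report)  # raises if out of window
        except NegativeAgeError:
            exclusions.append((report.case_id, "event_date precedes birth_date"))
            continue
        except AgeOutOfRangeError:
            exclusions.append((report.case_id, "age outside 0-12-year window"))
            continue
        retained.append(report)
    if exclusions:
        logger.info("age window: excluded %d of %d cases", len(exclusions), len(exclusions) + len(retained))
    return retained, exclusions


def filter_serious(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep only serious cases (seriousness other than ``not_serious``)."""
    reports = list(reports)
    kept = [r for r in reports if r.seriousness != "not_serious"]
    logger.info(
        "seriousness filter: excluded %d not-serious of %d cases",
        len(reports) - len(kept),
        len(reports),
    )
    return kept


def preprocess_reports(
    reports: Iterable[CaseReport],
) -> tuple[list[CaseReport], list[tuple[str, str]]]:
    """Full preprocessing: age window validation then serious-only filter."""
    in_window, exclusions = derive_ages(reports)
    serious = filter_serious(in_window)
    exclusions = exclusions + [
        (r.case_id, "not serious") for r in in_window if r.seriousness == "not_serious"
    ]
    return serious, exclusions


def write_exclusions(exclusions: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(exclusions, columns=["case_id", "reason"]).to_csv(path, index=False)
    return path
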