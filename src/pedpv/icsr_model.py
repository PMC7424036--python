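"""Domain model for individual case safety reports (ICSR) and its tidy CSV layout.

A database is a collection of :class:`CaseReport` objects, each carrying the
suspected drugs and the reported adverse-event terms of one spontaneous
report. On disk the database is a relational triple of CSV files keyed by
``case_id``:

* ``reports.csv``  — ``case_id,birth_date,event_date,age_days,gender,reporter_origin,seriousness``
* ``drugs.csv``    — ``case_id,drug_name,atc_level5,pharm_form,route,indication_icd``
* ``events.csv``   — ``case_id,event_term,soc``

All files are UTF-8, comma-delimited, with a mandatory header row. Dates are
ISO 8601. Missing values are empty cells (``gender=missing`` round-trips as
an empty cell, not the literal string).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled seriousness vocabulary, ordered from most to least severe.
SERIOUSNESS_LEVELS: tuple[str, ...] = (
    "death",
    "life_threatening",
    "prolonged_hospitalization",
    "congenital_abnormality",
    "persistent_disability",
    "medically_important",
    "not_serious",
)

#: The six serious outcomes (everything except ``not_serious``).
SERIOUS_LEVELS: tuple[str, ...] = SERIOUSNESS_LEVELS[:-1]

GENDERS: tuple[str, ...] = ("male", "female", "missing")
REPORTER_ORIGINS: tuple[str, ...] = ("hospital", "other", "missing")

MAX_DRUGS_PER_CASE = 6

REPORT_COLUMNS = [
    "case_id",
    "birth_date",
    "event_date",
    "age_days",
    "gender",
    "reporter_origin",
    "seriousness",
]
DRUG_COLUMNS = [
    "case_id",
    "drug_name",
    "atc_level5",
    "pharm_form",
    "route",
    "indication_icd",
]
EVENT_COLUMNS = ["case_id", "event_term", "soc"]


class SchemaError(ValueError):
    """A CSV file does not conform to the documented column schema."""


class IntegrityError(ValueError):
    """Cross-file referential or structural integrity is violated."""


def normalize_name(name: str) -> str:
    """Normalize a drug or event term: uppercase, trim, collapse inner blanks.

    Internal ``/`` is preserved so combination products (e.g.
    ``IMIPENEM/CILASTATIN``) remain a single suspected-drug entity.
    """
    return " ".join(str(name).split()).upper()


def most_severe(outcomes: Iterable[str]) -> str:
    """Collapse several seriousness outcomes to the single most severe one."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no seriousness outcomes supplied")
    for level in outcomes:
        if level not in SERIOUSNESS_LEVELS:
            raise ValueError(f"unknown seriousness value: {level!r}")
    return min(outcomes, key=SERIOUSNESS_LEVELS.index)


@dataclass
class EventEntry:
    """One adverse-event term reported within a case."""

    event_term: str
    soc: str = ""
    is_ime: bool = False

    def __post_init__(self) -> None:
        self.event_term = normalize_name(self.event_term)
        if not self.event_term:
            raise ValueError("event_term must be non-empty")


@dataclass
class DrugEntry:
    """One suspected drug within a case."""

    drug_name: str
    atc_level5: Optional[str] = None
    pharm_form: str = "indeterminate"
    route: str = "indeterminate"
    indication_icd: Optional[str] = None
    label_status: str = "unknown"

    def __post_init__(self) -> None:
        self.drug_name = normalize_name(self.drug_name)
        if self.atc_level5 is not None:
            self.atc_level5 = self.atc_level5.strip().upper() or None

    @property
    def atc_level1(self) -> Optional[str]:
        """Anatomical main group: the first letter of the ATC level-5 code."""
        return self.atc_level5[0] if self.atc_level5 else None


@dataclass
class CaseReport:
    """One spontaneous report: a patient, the suspected drugs, the events."""

    case_id: str
    seriousness: str
    gender: str = "missing"
    reporter_origin: str = "missing"
    birth_date: Optional[dt.date] = None
    event_date: Optional[dt.date] = None
    age_days: Optional[int] = None
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[EventEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seriousness not in SERIOUSNESS_LEVELS:
            raise ValueError(f"unknown seriousness value: {self.seriousness!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender value: {self.gender!r}")
        if self.reporter_origin not in REPORTER_ORIGINS:
            raise ValueError(
                f"unknown reporter_origin value: {self.reporter_origin!r}"
            )

    def validate(self) -> None:
        """Enforce structural invariants; raise IntegrityError on violation."""
        if not 1 <= len(self.drugs) <= MAX_DRUGS_PER_CASE:
            raise IntegrityError(
                f"case {self.case_id}: {len(self.drugs)} drug entries "
                f"(expected 1..{MAX_DRUGS_PER_CASE})"
            )
        if len(self.events) < 1:
            raise IntegrityError(f"case {self.case_id}: no event entries")
        if self.age_days is None and (
            self.birth_date is None or self.event_date is None
        ):
            raise IntegrityError(
                f"case {self.case_id}: age not derivable "
                "(need age_days or both birth_date and event_date)"
            )
        if self.age_days is not None and self.age_days < 0:
            raise IntegrityError(f"case {self.case_id}: negative age_days")

    @property
    def drug_names(self) -> set[str]:
        return {d.drug_name for d in self.drugs}

    @property
    def event_terms(self) -> set[str]:
        return {e.event_term for e in self.events}


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")


def _read_csv(path: Path) -> pd.DataFrame:
    # keep_default_na=False so empty cells come back as "" rather than NaN
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _parse_date(value: str, path: Path, case_id: str) -> Optional[dt.date]:
    if value == "":
        return None
    try:
        return dt.date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(f"{path}: case {case_id}: bad ISO date {value!r}") from exc


def read_database(
    reports_path: str | Path,
    drugs_path: str | Path,
    events_path: str | Path,
) -> list[CaseReport]:
    """Read a three-file tidy database into structured case reports.

    Duplicate ``(case_id, drug_name)`` or ``(case_id, event_term)`` rows are
    collapsed to a single entry with a logged warning. Orphan drug or event
    rows (case ids absent from the reports file) raise IntegrityError.
    """
    reports_path, drugs_path, events_path = (
        Path(reports_path),
        Path(drugs_path),
        Path(events_path),
    )
    reports_df = _read_csv(reports_path)
    drugs_df = _read_csv(drugs_path)
    events_df = _read_csv(events_path)
    _require_columns(reports_df, REPORT_COLUMNS, reports_path)
    _require_columns(drugs_df, DRUG_COLUMNS, drugs_path)
    _require_columns(events_df, EVENT_COLUMNS, events_path)

    if reports_df["case_id"].duplicated().any():
        dupes = reports_df.loc[reports_df["case_id"].duplicated(), "case_id"]
        raise IntegrityError(
            f"{reports_path}: duplicate case ids: {sorted(set(dupes))}"
        )

    known_ids = set(reports_df["case_id"])
    for df, path, kind in ((drugs_df, drugs_path, "drug"), (events_df, events_path, "event")):
        orphans = sorted(set(df["case_id"]) - known_ids)
        if orphans:
            raise IntegrityError(
                f"{path}: orphan {kind} rows for case ids not in "
                f"{reports_path.name}: {orphans}"
            )

    cases: dict[str, CaseReport] = {}
    for row in reports_df.itertuples(index=False):
        age_days = int(row.age_days) if row.age_days != "" else None
        case = CaseReport(
            case_id=row.case_id,
            seriousness=row.seriousness,
            gender=row.gender or "missing",
            reporter_origin=row.reporter_origin or "missing",
            birth_date=_parse_date(row.birth_date, reports_path, row.case_id),
            event_date=_parse_date(row.event_date, reports_path, row.case_id),
            age_days=age_days,
        )
        cases[case.case_id] = case

    seen_drugs: set[tuple[str, str]] = set()
    n_dup_drugs = 0
    for row in drugs_df.itertuples(index=False):
        key = (row.case_id, normalize_name(row.drug_name))
        if key in seen_drugs:
            n_dup_drugs += 1
            logger.warning("duplicate drug row collapsed: case %s, drug %s", *key)
            continue
        seen_drugs.add(key)
        cases[row.case_id].drugs.append(
            DrugEntry(
                drug_name=row.drug_name,
                atc_level5=row.atc_level5 or None,
                pharm_form=row.pharm_form or "indeterminate",
                route=row.route or "indeterminate",
                indication_icd=row.indication_icd or None,
            )
        )

    seen_events: set[tuple[str, str]] = set()
    n_dup_events = 0
    for row in events_df.itertuples(index=False):
        key = (row.case_id, normalize_name(row.event_term))
        if key in seen_events:
            n_dup_events += 1
            logger.warning("duplicate event row collapsed: case %s, event %s", *key)
            continue
        seen_events.add(key)
        cases[row.case_id].events.append(
            EventEntry(event_term=row.event_term, soc=row.soc)
        )

    if n_dup_drugs or n_dup_events:
        logger.warning(
            "collapsed %d duplicate drug rows and %d duplicate event rows",
            n_dup_drugs,
            n_dup_events,
        )

    result = list(cases.values())
    for case in result:
        case.validate()
    return result


def write_database(
    reports: Iterable[CaseReport], out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write case reports as the three-file tidy CSV layout.

    Returns the paths ``(reports.csv, drugs.csv, events.csv)``. The writer is
    the exact inverse of :func:`read_database` on valid databases.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report_rows, drug_rows, event_rows = [], [], []
    for case in reports:
        report_rows.append(
            {
                "case_id": case.case_id,
                "birth_date": case.birth_date.isoformat() if case.birth_date else "",
                "event_date": case.event_date.isoformat() if case.event_date else "",
                "age_days": "" if case.age_days is None else str(case.age_days),
                "gender": "" if case.gender == "missing" else case.gender,
                "reporter_origin": ""
                if case.reporter_origin == "missing"
                else case.reporter_origin,
                "seriousness": case.seriousness,
            }
        )
        for drug in case.drugs:
            drug_rows.append(
                {
                    "case_id": case.case_id,
                    "drug_name": drug.drug_name,
                    "atc_level5": drug.atc_level5 or "",
                    "pharm_form": drug.pharm_form,
                    "route": drug.route,
                    "indication_icd": drug.indication_icd or "",
                }
            )
        for event in case.events:
            event_rows.append(
                {"case_id": case.case_id, "event_term": event.event_term, "soc": event.soc}
            )

    paths = (
        out_dir / "reports.csv",
        out_dir / "drugs.csv",
        out_dir / "events.csv",
    )
    pd.DataFrame(report_rows, columns=REPORT_COLUMNS).to_csv(paths[0], index=False)
    pd.DataFrame(drug_rows, columns=DRUG_COLUMNS).to_csv(paths[1], index=False)
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(paths[2], index=False)
    return paths
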