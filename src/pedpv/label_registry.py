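"""Label-registry lookups: licensing, age-based off-label use, unlabelled events.

A :class:`LabelRecord` summarizes one drug's national label (summary of
product characteristics): whether the product is licensed, the approved age
interval in days, and the set of adverse-event terms the label describes.
Classification is age-based only: a licensed drug used outside its approved
age interval is off-label (OL); a drug with no registry record, or recorded
as not licensed, is unlicensed (UL).

Registry file format (``label_registry.csv``)::

    drug_name,licensed,min_age_days,max_age_days,labelled_event_terms

with ``labelled_event_terms`` a ``;``-separated list, empty cells meaning
"not recorded" for the age bounds. Term matching is exact on normalized
(uppercased, trimmed) strings; the registry must use the same vocabulary as
the events file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .icsr_model import CaseReport, DrugEntry, normalize_name

logger = logging.getLogger(__name__)

LABEL_STATUSES = ("on_label", "off_label", "unlicensed", "unknown")

REGISTRY_COLUMNS = [
    "drug_name",
    "licensed",
    "min_age_days",
    "max_age_days",
    "labelled_event_terms",
]


@dataclass(frozen=True)
class LabelRecord:
    """Licensing status, approved age interval and labelled ADR terms."""

    drug_name: str
    licensed: bool
    min_age_days: Optional[int] = None
    max_age_days: Optional[int] = None  # None = no upper bound
    labelled_event_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_name", normalize_name(self.drug_name))
        object.__setattr__(
            self,
            "labelled_event_terms",
            frozenset(normalize_name(t) for t in self.labelled_event_terms),
        )
        if (
            self.min_age_days is not None
            and self.max_age_days is not None
            and self.min_age_days > self.max_age_days
        ):
            raise ValueError(
                f"{self.drug_name}: min_age_days > max_age_days "
                f"({self.min_age_days} > {self.max_age_days})"
            )


Registry = Mapping[str, LabelRecord]


def build_registry(records: Iterable[LabelRecord]) -> dict[str, LabelRecord]:
    """Index records by normalized drug name."""
    return {rec.drug_name: rec for rec in records}


def classify_label_status(drug: DrugEntry, age_days: int, registry: Registry) -> str:
    """Classify one drug use for one patient age.

    * ``unlicensed`` — no registry record, or ``licensed`` is false;
    * ``unknown``    — licensed but no approved age interval recorded;
    * ``off_label``  — licensed, interval recorded, age outside it;
    * ``on_label``   — licensed, interval recorded, age inside it.
    """
    if age_days < 0:
        raise ValueError("age_days must be non-negative")
    record = registry.get(drug.drug_name)
    if record is None or not record.licensed:
        return "unlicensed"
    if record.min_age_days is None and record.max_age_days is None:
        return "unknown"
    lo = record.min_age_days if record.min_age_days is not None else 0
    if age_days < lo:
        return "off_label"
    if record.max_age_days is not None and age_days > record.max_age_days:
        return "off_label"
    return "on_label"


def flag_unlabelled_event(
    drug_name: str, event_term: str, registry: Registry
) -> bool:
    """True when the event term is not described in the drug's label.

    Drugs without a registry record have no label to consult; the event is
    flagged unlabelled (the drug itself is unlicensed).
    """
    record = registry.get(normalize_name(drug_name))
    if record is None:
        logger.debug(
            "unlabelled-event check for %s: no registry record (unlicensed)",
            drug_name,
        )
        return True
    return normalize_name(event_term) not in record.labelled_event_terms


def apply_label_classification(
    reports: Iterable[CaseReport], registry: Registry
) -> None:
    """Set ``label_status`` on every drug entry, in place.

    Uses each case's ``age_days`` (must be populated by preprocessing).
    """
    for report in reports:
        if report.age_days is None:
            raise ValueError(f"case {report.case_id}: age_days not derived yet")
        for drug in report.drugs:
            drug.label_status = classify_label_status(drug, report.age_days, registry)


# ---------------------------------------------------------------------------
# Registry I/O


def read_label_registry(path: str | Path) -> dict[str, LabelRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REGISTRY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        terms = [t for t in row.labelled_event_terms.split(";") if t.strip()]
        records.append(
            LabelRecord(
                drug_name=row.drug_name,
                licensed=row.licensed.strip().lower() in ("true", "1", "yes"),
                min_age_days=int(row.min_age_days) if row.min_age_days != "" else None,
                max_age_days=int(row.max_age_days) if row.max_age_days != "" else None,
                labelled_event_terms=frozenset(terms),
            )
        )
    return build_registry(records)


def write_label_registry(registry: Registry, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for rec in sorted(registry.values(), key=lambda r: r.drug_name):
        rows.append(
            {
                "drug_name": rec.drug_name,
                "licensed": str(rec.licensed).lower(),
                "min_age_days": "" if rec.min_age_days is None else rec.min_age_days,
                "max_age_days": "" if rec.max_age_days is None else rec.max_age_days,
                "labelled_event_terms": ";".join(sorted(rec.labelled_event_terms)),
            }
        )
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, index=False)
    return path
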