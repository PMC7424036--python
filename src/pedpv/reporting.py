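"""Descriptive study tables: the publication-style summary of a database.

Builds the five standard tables of a pediatric serious-ADR study:

1. seriousness x age-group case counts;
2. ATC level-1 distribution of suspected drug entries;
3. off-label use by seriousness (drug-entry counts);
4. suspected drugs involved in deaths, with off-label/unlicensed counts;
5. signals of disproportionate reporting with unlabelled-event flags.

Percentages use the stated denominators (cases for table 1, drug entries for
tables 2-3), printed with one decimal and a '.' separator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .association_stats import CountTable, ol_by_seriousness_table, seriousness_by_age_table
from .disproportionality import RorResult, results_to_frame
from .icsr_model import SERIOUS_LEVELS, CaseReport
from .label_registry import Registry

ATC_LEVEL1_NAMES = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatological",
    "G": "Genito urinary system and sex hormones",
    "H": "Systemic hormonal preparations",
    "J": "Anti-infectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculo-skeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products, insecticides and repellents",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}


class EmptySummaryError(ValueError):
    """No reports to summarize."""


def percentage(count: float, denominator: float, decimals: int = 1) -> float:
    """Share of ``count`` in ``denominator`` as a percentage, rounded."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round(100.0 * count / denominator, decimals)


@dataclass
class StudySummary:
    n_reports: int
    n_drug_entries: int
    mean_drugs_per_report: float
    seriousness_by_age: CountTable
    atc_level1_distribution: pd.DataFrame
    pharm_form_distribution: pd.DataFrame
    ol_summary: pd.DataFrame
    death_drug_table: pd.DataFrame
    sdr_table: pd.DataFrame


def _distribution(values: Sequence[str], total: int, key_col: str) -> pd.DataFrame:
    counts = pd.Series(values).value_counts().sort_index()
    return pd.DataFrame(
        {
            key_col: counts.index,
            "n": counts.to_numpy(),
            "pct": [percentage(int(c), total) for c in counts],
        }
    )


def _death_drug_table(
    reports: Sequence[CaseReport],
) -> pd.DataFrame:
    """Per-drug description of cases with a fatal outcome."""
    rows: dict[str, dict] = {}
    for case in reports:
        if case.seriousness != "death":
            continue
        socs = sorted({e.soc for e in case.events if e.soc})
        for drug in case.drugs:
            row = rows.setdefault(
                drug.drug_name,
                {
                    "atc_level1": drug.atc_level1 or "",
                    "indications": set(),
                    "n_reports": 0,
                    "n_ol_ul": 0,
                    "socs": set(),
                },
            )
            row["n_reports"] += 1
            if drug.label_status in ("off_label", "unlicensed"):
                row["n_ol_ul"] += 1
            if drug.indication_icd:
                row["indications"].add(drug.indication_icd)
            row["socs"].update(socs)
    records = [
        {
            "atc_level1": row["atc_level1"],
            "drug_name": name,
            "indication_icd": ";".join(sorted(row["indications"])),
            "n_reports": row["n_reports"],
            "n_ol_ul": row["n_ol_ul"],
            "event_socs": ";".join(sorted(row["socs"])),
        }
        for name, row in rows.items()
    ]
    df = pd.DataFrame(
        records,
        columns=[
            "atc_level1",
            "drug_name",
            "indication_icd",
            "n_reports",
            "n_ol_ul",
            "event_socs",
        ],
    )
    # grouped by anatomical main group, drugs alphabetical within group
    return df.sort_values(["atc_level1", "drug_name"]).reset_index(drop=True)


def summarize(
    reports: Sequence[CaseReport],
    signals: Sequence[RorResult] = (),
    registry: Optional[Registry] = None,
) -> StudySummary:
    """Build the full descriptive summary of a preprocessed database.

    Label classification must have run when off-label columns are wanted;
    otherwise every entry counts as not-off-label (status ``unknown``).
    """
    reports = list(reports)
    if not reports:
        raise EmptySummaryError("cannot summarize an empty database")
    n_reports = len(reports)
    drug_entries = [d for case in reports for d in case.drugs]
    n_entries = len(drug_entries)

    atc = _distribution(
        [d.atc_level1 or "?" for d in drug_entries], n_entries, "atc_level1"
    )
    atc.insert(1, "atc_group", [ATC_LEVEL1_NAMES.get(k, "Unknown") for k in atc["atc_level1"]])
    forms = _distribution([d.pharm_form for d in drug_entries], n_entries, "pharm_form")

    ol_table = ol_by_seriousness_table(reports)
    ol_rows = []
    for i, level in enumerate(SERIOUS_LEVELS):
        total = int(ol_table.counts[i].sum())
        n_ol = int(ol_table.counts[i, 0])
        ol_rows.append(
            {
                "seriousness": level,
                "n_drugs": total,
                "n_off_label": n_ol,
                "pct_off_label": percentage(n_ol, total, 0) if total else 0.0,
            }
        )
    ol_summary = pd.DataFrame(ol_rows)

    sdr_frame = results_to_frame([r for r in signals if r.is_sdr])

    return StudySummary(
        n_reports=n_reports,
        n_drug_entries=n_entries,
        mean_drugs_per_report=round(n_entries / n_reports, 1),
        seriousness_by_age=seriousness_by_age_table(reports),
        atc_level1_distribution=atc,
        pharm_form_distribution=forms,
        ol_summary=ol_summary,
        death_drug_table=_death_drug_table(reports),
        sdr_table=sdr_frame,
    )


def write_tables(summary: StudySummary, out_dir: str | Path) -> dict[str, Path]:
    """Write the five study tables as CSV files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t1 = pd.DataFrame(
        summary.seriousness_by_age.counts,
        index=summary.seriousness_by_age.row_labels,
        columns=summary.seriousness_by_age.col_labels,
    )
    t1["total"] = t1.sum(axis=1)
    t1["pct"] = [percentage(v, summary.n_reports) for v in t1["total"]]
    t1.index.name = "seriousness"

    paths = {
        "table1": out_dir / "table1_seriousness_by_age.csv",
        "table2": out_dir / "table2_atc.csv",
        "table3": out_dir / "table3_ol.csv",
        "table4": out_dir / "table4_deaths.csv",
        "table5": out_dir / "table5_sdr.csv",
        "pharm_forms": out_dir / "pharm_form_distribution.csv",
    }
    t1.to_csv(paths["table1"])
    summary.atc_level1_distribution.to_csv(paths["table2"], index=False)
    summary.ol_summary.to_csv(paths["table3"], index=False)
    summary.death_drug_table.to_csv(paths["table4"], index=False)
    summary.sdr_table.to_csv(paths["table5"], index=False)
    summary.pharm_form_distribution.to_csv(paths["pharm_forms"], index=False)
    return paths
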