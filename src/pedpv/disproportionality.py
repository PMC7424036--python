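"""Reporting-odds-ratio disproportionality screening of drug-event pairs.

For each drug P and event R, case-level counts form the 2x2 table

====  ========================  ==========================
      event R reported          event R not reported
====  ========================  ==========================
P     a                         b
~P    c                         d
====  ========================  ==========================

and the reporting odds ratio is ROR = (a*d)/(c*b). The counting unit is the
individual case: a case contributes at most 1 to each cell no matter how
many entries repeat the drug or the event.

The 95% confidence interval is Woolf's log-normal interval,
``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``. When c = 0 (every
report of the event names this drug) the ROR is undefined; the conventional
sentinel value 99.9 is assigned, flagging a possible signal, and no interval
is reported. When b = 0 or d = 0 the Haldane +0.5 correction is applied to
all four cells for estimation and the result is flagged as corrected.

A pair is a signal of disproportionate reporting (SDR) when the event is on
the important-medical-event (IME) list, the case count ``a`` meets the
threshold (>= 3 for drugs under additional monitoring, >= 5 otherwise), and
the CI lower bound exceeds 1 (sentinel tables qualify by convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import norm

from .icsr_model import CaseReport, normalize_name
from .label_registry import Registry, flag_unlabelled_event

logger = logging.getLogger(__name__)

SENTINEL_ROR = 99.9

STRATUM_A_3_TO_4 = "a_3_to_4"
STRATUM_A_GE_5 = "a_ge_5"
STRATUM_BELOW = "below_threshold"

SIGNALS_COLUMNS = [
    "drug_name",
    "event_term",
    "a",
    "b",
    "c",
    "d",
    "ror",
    "ci_lower",
    "ci_upper",
    "sentinel",
    "stratum",
    "ime_event",
    "on_monitoring_list",
    "is_sdr",
    "unlabelled_event",
]


class UndefinedPairError(ValueError):
    """ROR requested for a pair never reported together (a = 0)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Case-level 2x2 counts for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class RorResult:
    """Scored drug-event pair with its SDR verdict."""

    drug_name: str
    event_term: str
    table: ContingencyTable
    ror: float
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    sentinel: bool
    haldane_corrected: bool = False
    is_sdr: bool = False
    stratum: str = STRATUM_BELOW
    ime_event: bool = False
    on_monitoring_list: bool = False
    unlabelled_event: Optional[bool] = None


def build_contingency(
    reports: Sequence[CaseReport], drug_name: str, event_term: str
) -> ContingencyTable:
    """Count cases into the 2x2 table for one drug-event pair."""
    drug_name = normalize_name(drug_name)
    event_term = normalize_name(event_term)
    a = b = c = d = 0
    for case in reports:
        has_drug = drug_name in case.drug_names
        has_event = event_term in case.event_terms
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def _estimation_cells(table: ContingencyTable) -> tuple[float, float, float, float, bool]:
    """Cells used for estimation, with Haldane +0.5 when b or d is zero."""
    if table.b == 0 or table.d == 0:
        return table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5, True
    return float(table.a), float(table.b), float(table.c), float(table.d), False


def compute_ror(table: ContingencyTable) -> tuple[float, bool]:
    """Point estimate and sentinel flag for one table.

    Requires a >= 1. c = 0 yields the sentinel (99.9, True); b = 0 or d = 0
    is estimated on Haldane-corrected cells; otherwise the plain ratio.
    """
    if table.a == 0:
        raise UndefinedPairError("pair never reported together (a = 0)")
    if table.c == 0:
        return SENTINEL_ROR, True
    a, b, c, d, _ = _estimation_cells(table)
    return (a * d) / (c * b), False


def compute_ci(
    table: ContingencyTable, level: float = 0.95
) -> tuple[float, float]:
    """Woolf log-normal confidence interval for the ROR.

    Not defined for sentinel (c = 0) tables. Haldane-corrected cells are
    used when b = 0 or d = 0, matching :func:`compute_ror`.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if table.a == 0:
        raise UndefinedPairError("pair never reported together (a = 0)")
    if table.c == 0:
        raise ValueError("no confidence interval for sentinel (c = 0) tables")
    a, b, c, d, _ = _estimation_cells(table)
    z = norm.ppf(0.5 + level / 2.0)
    log_ror = math.log((a * d) / (c * b))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def score_pair(
    drug_name: str, event_term: str, table: ContingencyTable
) -> RorResult:
    """Assemble an unclassified result (no SDR verdict yet) for one pair."""
    ror, sentinel = compute_ror(table)
    corrected = (table.b == 0 or table.d == 0) and not sentinel
    if sentinel:
        lo = hi = None
    else:
        lo, hi = compute_ci(table)
    return RorResult(
        drug_name=normalize_name(drug_name),
        event_term=normalize_name(event_term),
        table=table,
        ror=ror,
        ci_lower=lo,
        ci_upper=hi,
        sentinel=sentinel,
        haldane_corrected=corrected,
    )


def detect_sdr(
    results: Iterable[RorResult],
    monitoring_list: Iterable[str],
    ime_list: Iterable[str],
) -> list[RorResult]:
    """Apply the SDR decision rule to scored pairs.

    is_sdr is true iff the event is an IME term, the case count meets its
    threshold (a >= 3 for additionally monitored drugs, a >= 5 otherwise)
    and the 95% lower bound strictly exceeds 1 (sentinel tables qualify).
    Pairs with a < 3 are kept with stratum ``below_threshold``, never SDR.
    """
    monitoring = {normalize_name(s) for s in monitoring_list}
    ime = {normalize_name(s) for s in ime_list}
    out = []
    for res in results:
        a = res.table.a
        if a < 1:
            raise UndefinedPairError("pair never reported together (a = 0)")
        monitored = res.drug_name in monitoring
        ime_event = res.event_term in ime
        if a >= 5:
            stratum = STRATUM_A_GE_5
        elif a >= 3:
            stratum = STRATUM_A_3_TO_4
        else:
            stratum = STRATUM_BELOW
        count_ok = (monitored and a >= 3) or a >= 5
        signal_stat = res.sentinel or (res.ci_lower is not None and res.ci_lower > 1)
        is_sdr = stratum != STRATUM_BELOW and ime_event and count_ok and signal_stat
        out.append(
            replace(
                res,
                stratum=stratum,
                ime_event=ime_event,
                on_monitoring_list=monitored,
                is_sdr=is_sdr,
            )
        )
    return out


def enumerate_pair_tables(
    reports: Sequence[CaseReport], min_a: int = 1
) -> dict[tuple[str, str], ContingencyTable]:
    """All drug-event pairs co-reported at least ``min_a`` times.

    Single pass over the database: per-case membership sets feed pairwise
    co-occurrence counts, from which each 2x2 table follows by margins.
    """
    n = len(reports)
    drug_counts: dict[str, int] = {}
    event_counts: dict[str, int] = {}
    pair_counts: dict[tuple[str, str], int] = {}
    for case in reports:
        drugs = case.drug_names
        events = case.event_terms
        for dname in drugs:
            drug_counts[dname] = drug_counts.get(dname, 0) + 1
        for ev in events:
            event_counts[ev] = event_counts.get(ev, 0) + 1
        for dname in drugs:
            for ev in events:
                pair_counts[(dname, ev)] = pair_counts.get((dname, ev), 0) + 1
    tables = {}
    for (dname, ev), a in pair_counts.items():
        if a < min_a:
            continue
        b = drug_counts[dname] - a
        c = event_counts[ev] - a
        d = n - a - b - c
        tables[(dname, ev)] = ContingencyTable(a, b, c, d)
    return tables


def screen(
    reports: Sequence[CaseReport],
    monitoring_list: Iterable[str],
    ime_list: Iterable[str],
    registry: Optional[Registry] = None,
    min_a: int = 3,
) -> list[RorResult]:
    """Full screening: enumerate, score (a >= min_a), classify, annotate.

    Pairs are scored only at a >= 3 (the screening threshold); the optional
    registry adds the unlabelled-event annotation used in signal tables.
    """
    tables = enumerate_pair_tables(reports, min_a=min_a)
    results = [score_pair(dname, ev, t) for (dname, ev), t in sorted(tables.items())]
    results = detect_sdr(results, monitoring_list, ime_list)
    if registry is not None:
        for res in results:
            res.unlabelled_event = flag_unlabelled_event(
                res.drug_name, res.event_term, registry
            )
    logger.info(
        "screened %d pairs (a >= %d) over %d cases: %d SDRs",
        len(results),
        min_a,
        len(reports),
        sum(r.is_sdr for r in results),
    )
    return results


# ---------------------------------------------------------------------------
# Term lists and output


def read_term_list(path: str | Path) -> set[str]:
    """One normalized term per line; '#' starts a comment."""
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.add(normalize_name(line))
    return terms


def write_term_list(terms: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "\n".join(sorted(normalize_name(t) for t in terms)) + "\n", encoding="utf-8"
    )
    return path


def results_to_frame(results: Sequence[RorResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "drug_name": r.drug_name,
                "event_term": r.event_term,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": round(r.ror, 4),
                "ci_lower": "" if r.ci_lower is None else round(r.ci_lower, 4),
                "ci_upper": "" if r.ci_upper is None else round(r.ci_upper, 4),
                "sentinel": r.sentinel,
                "stratum": r.stratum,
                "ime_event": r.ime_event,
                "on_monitoring_list": r.on_monitoring_list,
                "is_sdr": r.is_sdr,
                "unlabelled_event": "" if r.unlabelled_event is None else r.unlabelled_event,
            }
        )
    return pd.DataFrame(rows, columns=SIGNALS_COLUMNS)


def write_signals(results: Sequence[RorResult], path: str | Path) -> Path:
    path = Path(path)
    results_to_frame(results).to_csv(path, index=False)
    return path
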