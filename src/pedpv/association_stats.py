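"""Pearson chi-square tests of independence on report and drug-entry counts.

Two study tables are reproduced: seriousness x age group (unit: case
report) and off-label use x seriousness (unit: drug entry). Tests are plain
Pearson chi-square without continuity correction or small-cell exclusion;
the minimum expected count is reported so callers can warn when it falls
below 5 instead of silently altering the statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .icsr_model import SERIOUS_LEVELS, CaseReport
from .preprocess import AgeGroup, age_group_of

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """The table has an all-zero row or column; the test is undefined."""


@dataclass
class CountTable:
    """A labelled r x c grid of non-negative counts."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("need at least a 2 x 2 table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("grand total must be at least 1")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    min_expected_count: float


def chi_square_independence(table: CountTable) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an all-zero row or column")
    stat, p, df, expected = chi2_contingency(counts, correction=False)
    min_expected = float(expected.min())
    if min_expected < 5:
        logger.warning(
            "chi-square: minimum expected count %.2f < 5; asymptotic p-value "
            "may be unreliable",
            min_expected,
        )
    return ChiSquareResult(float(stat), int(df), float(p), min_expected)


def seriousness_by_age_table(reports: Sequence[CaseReport]) -> CountTable:
    """Case counts in the 6 serious outcomes x 5 pediatric age groups grid."""
    groups = [g.value for g in AgeGroup]
    counts = np.zeros((len(SERIOUS_LEVELS), len(groups)), dtype=np.int64)
    for case in reports:
        i = SERIOUS_LEVELS.index(case.seriousness)
        j = groups.index(age_group_of(case).value)
        counts[i, j] += 1
    return CountTable(list(SERIOUS_LEVELS), groups, counts)


def ol_by_seriousness_table(reports: Sequence[CaseReport]) -> CountTable:
    """Drug-entry counts: seriousness rows x (off-label, not-off-label).

    The counting unit is the drug entry, not the case. Entries with label
    status ``unknown`` (and ``unlicensed``) count as not-off-label; the
    unknown tally is logged so coverage is visible.
    """
    counts = np.zeros((len(SERIOUS_LEVELS), 2), dtype=np.int64)
    n_unknown = 0
    for case in reports:
        i = SERIOUS_LEVELS.index(case.seriousness)
        for drug in case.drugs:
            if drug.label_status == "off_label":
                counts[i, 0] += 1
            else:
                counts[i, 1] += 1
                if drug.label_status == "unknown":
                    n_unknown += 1
    if n_unknown:
        logger.info(
            "off-label table: %d drug entries with unknown label status "
            "counted as not-off-label",
            n_unknown,
        )
    return CountTable(list(SERIOUS_LEVELS), ["off_label", "not_off_label"], counts)


def drop_empty_margins(table: CountTable) -> CountTable:
    """Remove all-zero rows/columns (e.g. outcomes absent from a sample)."""
    keep_r = table.counts.sum(axis=1) > 0
    keep_c = table.counts.sum(axis=0) > 0
    return CountTable(
        [l for l, k in zip(table.row_labels, keep_r) if k],
        [l for l, k in zip(table.col_labels, keep_c) if k],
        table.counts[keep_r][:, keep_c],
    )
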