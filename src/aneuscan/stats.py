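"""Cohort stratification statistics: contingency tables and Pearson chi-square.

The subtype x CIN-status association is tested with the plain Pearson
chi-square (no continuity correction), statistic sum (O-E)^2/E with
expected counts from the row/column margins and df = (rows-1)(cols-1).
Fisher's exact test is offered as an alternative for sparse 2x2 tables.
Percentages follow the cohort report style of printing two decimals with
the trailing digits truncated (12/39 -> 30.76).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .calling import CIN_NEGATIVE, CIN_POSITIVE, QC_FAILED, SampleCINResult

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "pearson_chi_square",
    "fisher_exact",
    "proportion_summary",
    "build_cohort_table",
    "subtype_association",
]

UNDETERMINED = "N/A"


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("need at least 2 rows and 2 columns")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be > 0")

    def drop_row(self, label: str) -> "ContingencyTable":
        keep = [i for i, r in enumerate(self.row_labels) if r != label]
        return ContingencyTable(
            row_labels=[self.row_labels[i] for i in keep],
            col_labels=list(self.col_labels),
            counts=self.counts[keep],
        )


@dataclass
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    expected_counts: np.ndarray = field(repr=False)
    min_expected: float = 0.0

    @property
    def low_expected_warning(self) -> bool:
        """Asymptotic chi-square is doubtful when any expected count < 5."""
        return self.min_expected < 5

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "df": int(self.degrees_of_freedom),
            "p_value": float(self.p_value),
            "min_expected": float(self.min_expected),
            "low_expected_warning": bool(self.low_expected_warning),
        }


def pearson_chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction."""
    counts = np.asarray(table.counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate margins: all-zero row or column")
    statistic, p, df, expected = sps.chi2_contingency(counts, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        degrees_of_freedom=int(df),
        p_value=float(p),
        expected_counts=expected,
        min_expected=float(expected.min()),
    )


def fisher_exact(table: ContingencyTable) -> float:
    """Fisher's exact p for a 2x2 table (alternative to the chi-square)."""
    if table.counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return float(sps.fisher_exact(table.counts)[1])


def proportion_summary(positive: int, total: int) -> float:
    """Percentage 100*positive/total printed to two truncated decimals.

    Truncation (not half-up rounding) matches the reporting style in which
    12/39 prints as 30.76%.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= positive <= total:
        raise ValueError("need 0 <= positive <= total")
    return math.floor(100.0 * positive / total * 100) / 100


def build_cohort_table(
    results: list[SampleCINResult],
    subtypes: dict[str, str],
    undetermined_label: str = UNDETERMINED,
) -> tuple[ContingencyTable, int]:
    """Subtype x CIN-status counts; returns (table, n_qc_dropped).

    QC-failed samples are excluded from the table; samples without a
    subtype label fall into the undetermined row, which stays in the table
    but is excluded from the default association test.
    """
    rows: dict[str, list[int]] = {}
    dropped = 0
    order: list[str] = []
    for r in results:
        if r.status == QC_FAILED:
            dropped += 1
            continue
        if r.status not in (CIN_POSITIVE, CIN_NEGATIVE):
            raise ValueError(f"unknown status {r.status!r}")
        subtype = subtypes.get(r.sample_id, undetermined_label)
        if subtype not in rows:
            rows[subtype] = [0, 0]
            order.append(subtype)
        rows[subtype][0 if r.status == CIN_POSITIVE else 1] += 1
    if not order:
        raise ValueError("no evaluable samples")
    table = ContingencyTable(
        row_labels=order,
        col_labels=[CIN_POSITIVE, CIN_NEGATIVE],
        counts=np.array([rows[r] for r in order]),
    )
    return table, dropped


def subtype_association(
    table: ContingencyTable,
    exclude_undetermined: bool = True,
    undetermined_label: str = UNDETERMINED,
) -> ChiSquareResult:
    """Chi-square on the subtype table, dropping the undetermined row by
    default (the defined-subtype contrast is the scientific question)."""
    if exclude_undetermined and undetermined_label in table.row_labels:
        table = table.drop_row(undetermined_label)
    return pearson_chi_square(table)
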