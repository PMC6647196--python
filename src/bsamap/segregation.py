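"""Mendelian segregation tests on phenotype count tables.

A single dominant locus predicts 3:1 (fuzzless:fuzzy) segregation in an F2
and 1:1 in a backcross to the recessive parent. The chi-square
goodness-of-fit test is computed without continuity correction — the
convention that reproduces the published statistics for these population
sizes (0.02 for 3004:1006 vs 3:1; 0.87 for 315:292 vs 1:1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "SegregationTable",
    "ChiSquareResult",
    "chi_square_gof",
    "observed_ratio",
    "read_counts_tsv",
    "segregation_report",
]


@dataclass(frozen=True)
class SegregationTable:
    label: str
    n_fuzzless: int
    n_fuzzy: int
    expected_ratio: tuple[float, float] = (3.0, 1.0)  # fuzzless : fuzzy

    def __post_init__(self) -> None:
        if self.n_fuzzless < 0 or self.n_fuzzy < 0:
            raise ValueError("counts must be non-negative")
        if self.n_fuzzless + self.n_fuzzy == 0:
            raise ValueError("total count must be positive")
        if min(self.expected_ratio) <= 0:
            raise ValueError("expected ratio components must be positive")

    @property
    def total(self) -> int:
        return self.n_fuzzless + self.n_fuzzy


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    observed_ratio: float  # majority / minority


def chi_square_gof(table: SegregationTable) -> ChiSquareResult:
    """Chi-square goodness of fit against the expected segregation ratio.

    Expected counts are the total split by the expected ratio; df = 1 for
    the two phenotype classes; no Yates correction.
    """
    observed = [table.n_fuzzless, table.n_fuzzy]
    w = sum(table.expected_ratio)
    expected = [table.total * r / w for r in table.expected_ratio]
    if min(expected) == 0:
        raise ValueError("zero expected count")
    chi2, p = stats.chisquare(observed, expected)
    return ChiSquareResult(
        chi2=float(chi2), df=1, p=float(p), observed_ratio=observed_ratio(table)
    )


def observed_ratio(table: SegregationTable) -> float:
    """Majority/minority phenotype ratio, rounded to 2 decimal places."""
    minority = min(table.n_fuzzless, table.n_fuzzy)
    majority = max(table.n_fuzzless, table.n_fuzzy)
    if minority == 0:
        raise ZeroDivisionError("minority phenotype class is empty")
    return round(majority / minority, 2)


def read_counts_tsv(path) -> list[SegregationTable]:
    """Read a phenotype count table (label, n_fuzzless, n_fuzzy, expected_*)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SegregationTable(
            label=str(row["label"]),
            n_fuzzless=int(row["n_fuzzless"]),
            n_fuzzy=int(row["n_fuzzy"]),
            expected_ratio=(float(row["expected_fuzzless"]), float(row["expected_fuzzy"])),
        )
        for _, row in df.iterrows()
    ]


def segregation_report(tables) -> pd.DataFrame:
    rows = []
    for t in tables:
        res = chi_square_gof(t)
        rows.append(
            {
                "label": t.label,
                "total": t.total,
                "n_fuzzless": t.n_fuzzless,
                "n_fuzzy": t.n_fuzzy,
                "observed_ratio": f"{res.observed_ratio:.2f}:1",
                "expected_ratio": f"{t.expected_ratio[0]:g}:{t.expected_ratio[1]:g}",
                "chi2": round(res.chi2, 2),
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
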