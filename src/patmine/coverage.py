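"""Per-year disease coverage statistics.

Coverage of a disease in a year is the number of patent documents
mentioning it divided by the number of documents mentioning at least one
disease that year (document-level counting: ten mentions in one document
count once).  An alternative denominator — all biomedical documents in the
year, whether or not they mention a disease — is available via a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .concepts import DiseaseAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseYearMatrix",
    "CoverageTable",
    "tabulate",
    "coverage",
    "diseases_covered_per_year",
    "top_k",
]


@dataclass
class DiseaseYearMatrix:
    """Distinct-document counts per (root PheCode, year).

    ``denominators`` counts documents with a non-empty root set per year;
    ``totals`` counts all annotated documents per year (for the alternative
    denominator reading).
    """

    counts: pd.DataFrame  # index: phecode, columns: year (int)
    denominators: pd.Series  # index: year
    totals: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.totals is None:
            self.totals = self.denominators.copy()
        for year in self.counts.columns:
            col_max = self.counts[year].max() if len(self.counts) else 0
            if col_max > self.denominators.get(year, 0):
                raise ValueError(f"year {year}: a count exceeds its denominator")


@dataclass
class CoverageTable:
    coverage: pd.DataFrame  # index: phecode, columns: year, values in [0, 1]

    def to_csv(self, path: str | Path) -> None:
        self.coverage.to_csv(path, index_label="phecode")


def tabulate(
    annotations: Iterable[DiseaseAnnotation],
    doc_years: Mapping[str, int],
) -> DiseaseYearMatrix:
    """Count distinct documents per (disease, year).

    Every annotated doc_id must have a year in ``doc_years``; offenders are
    collected and reported together.
    """
    missing: list[str] = []
    counts: dict[str, dict[int, int]] = {}
    denom: dict[int, int] = {}
    totals: dict[int, int] = {}
    for ann in annotations:
        year = doc_years.get(ann.doc_id)
        if year is None:
            missing.append(ann.doc_id)
            continue
        totals[year] = totals.get(year, 0) + 1
        if ann.root_phecodes:
            denom[year] = denom.get(year, 0) + 1
            for root in ann.root_phecodes:
                counts.setdefault(root, {})[year] = (
                    counts.setdefault(root, {}).get(year, 0) + 1
                )
    if missing:
        raise ValueError(f"annotated doc_ids without a year: {sorted(missing)}")
    years = sorted(totals)
    frame = pd.DataFrame(
        [[counts.get(d, {}).get(y, 0) for y in years] for d in sorted(counts)],
        index=sorted(counts),
        columns=years,
        dtype=int,
    )
    denominators = pd.Series({y: denom.get(y, 0) for y in years}, dtype=int)
    total_series = pd.Series({y: totals[y] for y in years}, dtype=int)
    return DiseaseYearMatrix(counts=frame, denominators=denominators, totals=total_series)


def coverage(
    matrix: DiseaseYearMatrix, denominator: str = "mentioning"
) -> CoverageTable:
    """coverage[d, t] = counts[d, t] / denominator[t].

    ``denominator="mentioning"`` divides by documents mentioning >= 1
    disease (the default reading); ``"all"`` divides by all documents in the
    year.  Zero-denominator years are dropped rather than divided by zero.
    """
    if denominator == "mentioning":
        denom = matrix.denominators
    elif denominator == "all":
        denom = matrix.totals
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    keep = [y for y in matrix.counts.columns if denom.get(y, 0) > 0]
    cov = matrix.counts[keep].astype(float).div(denom[keep], axis=1)
    return CoverageTable(coverage=cov)


def diseases_covered_per_year(matrix: DiseaseYearMatrix) -> pd.Series:
    """Number of root PheCodes with a nonzero document count, per year."""
    if matrix.counts.empty:
        return pd.Series(dtype=int)
    return (matrix.counts > 0).sum(axis=0)


def top_k(
    table: CoverageTable, k: int, ranking: str = "mean-over-years"
) -> pd.DataFrame:
    """Rank diseases by coverage, descending; ties break lexicographically.

    Returns a frame with columns (rank, phecode, statistic).  If ``k``
    exceeds the number of diseases, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if ranking == "mean-over-years":
        stat = table.coverage.mean(axis=1)
    elif ranking == "final-year":
        stat = table.coverage[table.coverage.columns[-1]]
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    if k > len(stat):
        warnings.warn(
            f"k={k} exceeds the number of diseases ({len(stat)}); returning all"
        )
        k = len(stat)
    ordered = sorted(stat.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "phecode": [p for p, _ in ordered],
            "statistic": [s for _, s in ordered],
        }
    )
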