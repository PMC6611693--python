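"""Research Opportunity Index (ROI), Public Health Index (PHI), and the
variance-inflation-factor (VIF) multicollinearity audit.

Four disease-level measures are tracked per year: disease burden
(treatment cost per million people), publications, clinical trials, and
patent documents.  Raw values Y are inflation-prone and unit-incommensurate,
so each measure-year is normalized to shares X summing to one across
diseases.  With burden share X_b and composite resource share
R = w_r X_r + w_c X_c + w_p X_p:

* ROI is the signed fold ratio rho = X_b / R: +rho when rho >= 1
  (understudied — burden exceeds resources) and -1/rho when rho < 1
  (overstudied).  Exact alignment gives +1.
* PHI(t) = 1/2 * sum_d |X_bd(t) - R_d(t)|, the total-variation distance
  between the burden and resource share distributions; 0 means perfect
  alignment, smaller is better.

Zero shares yield explicit sentinels rather than infinities so tabular
exports stay well defined.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "RESOURCES",
    "MeasureTable",
    "NormalizedTable",
    "normalize",
    "resource_composite",
    "roi",
    "phi",
    "vif",
]

MEASURES = ("burden", "publications", "trials", "patents")
RESOURCES = ("publications", "trials", "patents")

#: sentinel labels for undefined fold ratios
OVER_UNBOUNDED = "overstudied-unbounded"
UNDER_UNBOUNDED = "understudied-unbounded"
UNDEFINED = "undefined"


@dataclass
class MeasureTable:
    """Raw disease x year values for the four measures (tidy layout)."""

    data: pd.DataFrame  # columns: measure, phecode, year, value

    def __post_init__(self) -> None:
        required = {"measure", "phecode", "year", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"measure table needs columns {sorted(required)}")
        unknown = set(self.data["measure"]) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures {sorted(unknown)}")
        if (self.data["value"] < 0).any():
            raise ValueError("measure values must be nonnegative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasureTable":
        return cls(pd.read_csv(path, dtype={"phecode": str}))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def wide(self, measure: str) -> pd.DataFrame:
        """Pivot one measure to a (phecode x year) frame, missing -> 0."""
        sub = self.data[self.data["measure"] == measure]
        return (
            sub.pivot_table(
                index="phecode", columns="year", values="value", fill_value=0.0
            )
            .sort_index()
            .astype(float)
        )

    def window(self, start: int, end: int) -> "MeasureTable":
        mask = (self.data["year"] >= start) & (self.data["year"] <= end)
        return MeasureTable(self.data[mask].reset_index(drop=True))


@dataclass
class NormalizedTable:
    """Per measure-year shares X: each column sums to one over diseases."""

    X: dict[str, pd.DataFrame]  # measure -> phecode x year shares

    def __post_init__(self) -> None:
        frames = list(self.X.values())
        idx, cols = frames[0].index, frames[0].columns
        for f in frames[1:]:
            if not (f.index.equals(idx) and f.columns.equals(cols)):
                raise ValueError("normalized measures must share index/columns")

    @property
    def years(self) -> list[int]:
        return list(next(iter(self.X.values())).columns)

    @property
    def phecodes(self) -> list[str]:
        return list(next(iter(self.X.values())).index)


def normalize(table: MeasureTable) -> NormalizedTable:
    """X_nd(t) = Y_nd(t) / sum_d' Y_nd'(t), within each measure-year.

    Raises on an all-zero measure-year, naming the offending (measure, year).
    """
    X: dict[str, pd.DataFrame] = {}
    # align all measures on the union of phecodes/years
    wides = {m: table.wide(m) for m in MEASURES}
    all_phecodes = sorted(set().union(*(w.index for w in wides.values())))
    all_years = sorted(set().union(*(w.columns for w in wides.values())))
    for m, w in wides.items():
        w = w.reindex(index=all_phecodes, columns=all_years, fill_value=0.0)
        sums = w.sum(axis=0)
        zero_years = [int(y) for y in sums.index[sums <= 0]]
        if zero_years:
            raise ValueError(
                f"measure {m!r} has all-zero values in year(s) {zero_years}"
            )
        X[m] = w.div(sums, axis=1)
    return NormalizedTable(X=X)


def _resolve_weights(weights: Mapping[str, float] | None) -> dict[str, float]:
    if weights is None:
        return {m: 1.0 / 3.0 for m in RESOURCES}
    w = {m: float(weights[m]) for m in RESOURCES}
    if any(v < 0 for v in w.values()):
        raise ValueError("resource weights must be nonnegative")
    total = sum(w.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"resource weights must sum to 1, got {total}")
    return w


def resource_composite(
    X: NormalizedTable, weights: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """R_d(t) = sum over resource measures of w_n * X_nd(t); columns sum to 1."""
    w = _resolve_weights(weights)
    R = sum(w[m] * X.X[m] for m in RESOURCES)
    return R


@dataclass
class ROISeries:
    """Signed fold-ratio ROI per (phecode, year), with components."""

    table: pd.DataFrame  # columns: phecode, year, roi, x_burden, resource, sentinel

    def wide(self) -> pd.DataFrame:
        return self.table.pivot(index="phecode", columns="year", values="roi")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def roi(
    X: NormalizedTable, weights: Mapping[str, float] | None = None
) -> ROISeries:
    """Signed fold imbalance between burden share and composite resource share.

    roi = rho when rho = X_b/R >= 1 (positive, understudied) and -1/rho when
    rho < 1 (negative, overstudied); |roi| >= 1 always.  Zero shares produce
    sentinel rows with roi = NaN.
    """
    R = resource_composite(X, weights)
    Xb = X.X["burden"]
    rows = []
    for phecode in X.phecodes:
        for year in X.years:
            xb = float(Xb.at[phecode, year])
            r = float(R.at[phecode, year])
            sentinel = ""
            if xb == 0.0 and r == 0.0:
                value, sentinel = np.nan, UNDEFINED
            elif xb == 0.0:
                value, sentinel = np.nan, OVER_UNBOUNDED
            elif r == 0.0:
                value, sentinel = np.nan, UNDER_UNBOUNDED
            else:
                rho = xb / r
                value = rho if rho >= 1.0 else -1.0 / rho
            rows.append(
                {
                    "phecode": phecode,
                    "year": year,
                    "roi": value,
                    "x_burden": xb,
                    "resource": r,
                    "sentinel": sentinel,
                }
            )
    return ROISeries(table=pd.DataFrame(rows))


def phi(
    X: NormalizedTable, weights: Mapping[str, float] | None = None
) -> pd.Series:
    """PHI(t) = 1/2 * sum_d |X_bd(t) - R_d(t)| in [0, 1]; 0 iff aligned."""
    R = resource_composite(X, weights)
    diff = (X.X["burden"] - R).abs().sum(axis=0) / 2.0
    diff.name = "phi"
    return diff


def vif(
    X: NormalizedTable, year: int | None = None
) -> pd.Series:
    """Variance inflation factor per measure over disease share vectors.

    Each measure's cross-disease vector is regressed (with intercept) on the
    other three; VIF = 1/(1 - R^2).  By default disease-year rows are pooled
    over all years; pass ``year`` for a single-year audit.  Perfect
    collinearity reports ``inf`` with a warning.
    """
    years = [year] if year is not None else X.years
    cols = {}
    for m in MEASURES:
        cols[m] = np.concatenate([X.X[m][y].to_numpy() for y in years])
    n = len(next(iter(cols.values())))
    if n < 5:
        raise ValueError("VIF needs at least 5 disease rows")
    out = {}
    for m in MEASURES:
        y_vec = cols[m]
        others = [cols[o] for o in MEASURES if o != m]
        A = np.column_stack([np.ones(n)] + others)
        coef, _, _, _ = np.linalg.lstsq(A, y_vec, rcond=None)
        resid = y_vec - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y_vec - y_vec.mean()) ** 2).sum())
        if ss_tot == 0.0:
            r2 = 0.0  # constant vector: nothing to inflate
        else:
            r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"measure {m!r} is perfectly collinear; VIF infinite")
            out[m] = np.inf
        else:
            out[m] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
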