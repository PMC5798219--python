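"""Hardship index and life-expectancy disparity summaries.

The Economic Hardship Index (EHI) is a composite of six socioeconomic
indicators — crowded housing, poverty, unemployment, low educational
attainment, population dependency, and low income.  Each indicator is
min–max standardized across units to [0, 100] and the six standardized
components are averaged with equal weight; higher scores mean more
hardship.  Indicators must be oriented so that larger = worse before
scoring (use ``invert`` for columns on the opposite scale, e.g. median
income).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .reliability import AssessedEstimate

__all__ = [
    "EHI_INDICATORS",
    "AssociationResult",
    "compute_ehi",
    "le_gap",
    "le_hardship_association",
]

EHI_INDICATORS = (
    "crowded_housing",
    "poverty",
    "unemployment",
    "low_educational_attainment",
    "population_dependency",
    "low_income",
)


@dataclass(frozen=True)
class AssociationResult:
    coefficient: float
    n: int
    method: str
    degenerate: bool = False


def compute_ehi(
    indicators: pd.DataFrame, invert: tuple[str, ...] = ()
) -> pd.Series:
    """EHI scores in [0, 100], indexed by unit_id.

    ``indicators`` must carry exactly the six EHI columns (index =
    unit_id) with no missing values.  Columns named in ``invert`` are
    flipped (larger raw value = less hardship) before standardization.
    An indicator constant across units cannot be standardized; it
    contributes 0 to every score and triggers a warning.
    """
    missing = set(EHI_INDICATORS) - set(indicators.columns)
    if missing:
        raise DataError(f"missing EHI indicator columns: {sorted(missing)}")
    if len(indicators) < 2:
        raise DataError("EHI standardization requires at least 2 units")
    if indicators[list(EHI_INDICATORS)].isna().any().any():
        raise DataError("EHI indicators contain missing values")

    standardized = pd.DataFrame(index=indicators.index, dtype=float)
    for col in EHI_INDICATORS:
        x = indicators[col].astype(float)
        if col in invert:
            x = -x
        span = x.max() - x.min()
        if span == 0:
            warnings.warn(
                f"EHI indicator {col!r} is constant across units; "
                "it contributes 0 to every score",
                stacklevel=2,
            )
            standardized[col] = 0.0
        else:
            standardized[col] = 100.0 * (x - x.min()) / span
    return standardized.mean(axis=1).rename("ehi")


def le_gap(estimates: list[AssessedEstimate]) -> tuple[float, str, str]:
    """Gap in years between the longest- and shortest-lived reliable
    units; returns (gap, argmin unit, argmax unit).  Suppressed and
    excluded units never contribute."""
    reliable = [e for e in estimates if e.reliable and e.result is not None]
    if len(reliable) < 2:
        raise DataError("le_gap requires at least 2 reliable estimates")
    lo = min(reliable, key=lambda e: e.result.e0)
    hi = max(reliable, key=lambda e: e.result.e0)
    return hi.result.e0 - lo.result.e0, lo.unit_id, hi.unit_id


def le_hardship_association(
    le: pd.Series, ehi: pd.Series, method: str = "spearman"
) -> AssociationResult:
    """Correlation between per-unit e0 and EHI score, paired on index.

    Spearman (default) is robust to nonlinearity in the LE–hardship
    relationship; Pearson is available for linear summaries.  Zero
    variance in either variable leaves the coefficient undefined
    (NaN, ``degenerate=True``).
    """
    if method not in ("spearman", "pearson"):
        raise DataError(f"unknown association method {method!r}")
    paired = pd.concat([le.rename("le"), ehi.rename("ehi")], axis=1, join="inner").dropna()
    n = len(paired)
    if n < 3:
        raise DataError("association requires at least 3 paired units")
    if paired["le"].nunique() == 1 or paired["ehi"].nunique() == 1:
        return AssociationResult(float("nan"), n, method, degenerate=True)
    if method == "spearman":
        coef = stats.spearmanr(paired["le"], paired["ehi"]).statistic
    else:
        coef = stats.pearsonr(paired["le"], paired["ehi"]).statistic
    return AssociationResult(float(coef), n, method)
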