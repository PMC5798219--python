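"""Adjusted Chiang II abridged life tables.

Builds period life tables from age-banded death and person-year counts
and estimates the sampling variance of life expectancy at birth (e0).
The variance estimator is Chiang's, with an added term for the
open-ended terminal interval ("adjusted" Chiang II): without it, the
variance of e0 is understated in small populations because the terminal
rate m_w is itself estimated from few deaths.

Notation follows standard demographic usage: for band i with width n_i
and fraction-of-interval-lived a_i,

    m_i = D_i / P_i                       central death rate
    q_i = n_i m_i / (1 + n_i (1-a_i) m_i) probability of dying in band
    l_i, d_i, L_i, T_i, e_i               the usual life-table columns

and the variance of e0 is

    S^2_e0 = (1/l_0^2) * sum_{i<w} l_i^2 [(1-a_i) n_i + e_{i+1}]^2 S^2_qi
             + (l_w/l_0)^2 / (m_w^2 D_w)

with S^2_qi = q_i^2 (1-q_i) / D_i (zero when D_i = 0).  The second term
is the terminal-interval adjustment: the delta-method variance of
e_w = 1/m_w under Poisson-distributed terminal deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bands import AgeBandScheme
from .errors import DataError, FinalBandError, ZeroExposureDeathsError

__all__ = [
    "UnitCounts",
    "LifeTableResult",
    "central_death_rates",
    "death_probabilities",
    "build_life_table",
    "adjusted_variance",
    "confidence_interval",
    "compute_life_table",
]

DEFAULT_RADIX = 100_000.0

# cell-level quality flags attached to LifeTableResult.flags
FLAG_ZERO_EXPOSURE = "ZERO_EXPOSURE"
FLAG_Q_CLAMPED = "Q_CLAMPED"


@dataclass
class UnitCounts:
    """Age-banded deaths and person-years for one geographic unit.

    ``person_years`` already incorporates the observation window: a unit
    of 1,000 residents observed for 5 years contributes 5,000
    person-years-at-risk in total.
    """

    unit_id: str
    deaths: np.ndarray
    person_years: np.ndarray
    years_covered: int = 1
    gq_fraction: float | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        if self.deaths.shape != self.person_years.shape:
            raise DataError(
                f"unit {self.unit_id!r}: deaths and person_years must have "
                "one entry per age band"
            )
        if np.any(self.deaths < 0) or np.any(self.person_years < 0):
            raise DataError(f"unit {self.unit_id!r}: negative counts")

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())


@dataclass
class LifeTableResult:
    """Full abridged life table plus e0, its SE/CI and variance parts."""

    unit_id: str
    m: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray
    e0: float
    var_e0: float = float("nan")
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_level: float = 0.95
    variance_components: np.ndarray | None = None
    flags: set[str] = field(default_factory=set)


def _finite_widths(scheme: AgeBandScheme) -> np.ndarray:
    n = np.array(scheme.widths, dtype=float)
    n[-1] = np.nan  # open-ended; never used arithmetically
    return n


def central_death_rates(counts: UnitCounts, scheme: AgeBandScheme) -> tuple[np.ndarray, set[str]]:
    """Per-band central rates m_i = D_i / P_i, with the zero-cell policy.

    Closed bands with D_i = 0 and P_i = 0 get m_i = 0 plus a
    ZERO_EXPOSURE flag; deaths without exposure are a hard error; a
    terminal band with no deaths or no exposure makes the whole
    estimate non-computable.
    """
    D, P = counts.deaths, counts.person_years
    if len(D) != len(scheme):
        raise DataError(
            f"unit {counts.unit_id!r}: {len(D)} bands of counts for a "
            f"{len(scheme)}-band scheme"
        )
    w = scheme.final_index
    if P[w] <= 0 or D[w] <= 0:
        raise FinalBandError(
            f"unit {counts.unit_id!r}: terminal band {scheme.labels[w]!r} has "
            f"D={D[w]:g}, P={P[w]:g}; the terminal rate m_w must be positive"
        )
    flags: set[str] = set()
    m = np.zeros(len(D))
    for i in range(len(D)):
        if P[i] > 0:
            m[i] = D[i] / P[i]
        elif D[i] > 0:
            raise ZeroExposureDeathsError(
                f"unit {counts.unit_id!r}, band {scheme.labels[i]!r}: "
                f"{D[i]:g} deaths with zero person-years"
            )
        else:
            flags.add(FLAG_ZERO_EXPOSURE)
    return m, flags


def death_probabilities(m: np.ndarray, scheme: AgeBandScheme) -> tuple[np.ndarray, set[str]]:
    """Chiang conversion of central rates to death probabilities.

    q_i = n_i m_i / (1 + n_i (1-a_i) m_i) for closed bands; q_w = 1.
    Values that exceed 1 (implausibly high rates in wide bands) are
    clamped to 1 and flagged rather than raising.
    """
    m = np.asarray(m, dtype=float)
    w = scheme.final_index
    if m[w] <= 0:
        raise FinalBandError("terminal rate m_w must be positive")
    n = _finite_widths(scheme)
    a = np.array(scheme.fractions_lived)
    q = np.ones_like(m)
    closed = np.arange(len(m)) < w
    q[closed] = (n[closed] * m[closed]) / (1.0 + n[closed] * (1.0 - a[closed]) * m[closed])
    flags: set[str] = set()
    if np.any(q[closed] > 1.0):
        q = np.minimum(q, 1.0)
        flags.add(FLAG_Q_CLAMPED)
    return q, flags


def build_life_table(
    q: np.ndarray,
    m: np.ndarray,
    scheme: AgeBandScheme,
    radix: float = DEFAULT_RADIX,
    unit_id: str = "",
) -> LifeTableResult:
    """Assemble the life-table columns from q and m (no variance yet)."""
    q = np.asarray(q, dtype=float)
    m = np.asarray(m, dtype=float)
    w = scheme.final_index
    if m[w] <= 0:
        raise FinalBandError("terminal rate m_w must be positive")
    n = _finite_widths(scheme)
    a = np.array(scheme.fractions_lived)

    k = len(q)
    l = np.empty(k)
    d = np.empty(k)
    L = np.empty(k)
    l[0] = radix
    for i in range(k):
        d[i] = l[i] * q[i]
        if i < w:
            l_next = l[i] - d[i]
            L[i] = n[i] * (l_next + a[i] * d[i])
            l[i + 1] = l_next
        else:
            L[i] = l[i] / m[i]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)
    return LifeTableResult(
        unit_id=unit_id, m=m, q=q, l=l, d=d, L=L, T=T, e=e, e0=float(e[0])
    )


def adjusted_variance(
    table: LifeTableResult, deaths: np.ndarray, scheme: AgeBandScheme
) -> LifeTableResult:
    """Attach the adjusted Chiang II variance of e0 to a built table.

    Fills ``var_e0``, ``se`` and ``variance_components`` (per-band
    contributions on the var_e0 scale; the last entry is the
    terminal-interval adjustment term).
    """
    D = np.asarray(deaths, dtype=float)
    w = scheme.final_index
    if D[w] <= 0:
        raise FinalBandError("terminal band has no deaths; variance not computable")
    n = _finite_widths(scheme)
    a = np.array(scheme.fractions_lived)
    q, l, e, m = table.q, table.l, table.e, table.m

    comps = np.zeros(len(D))
    l0 = l[0]
    for i in range(w):
        if D[i] > 0:
            s2_q = q[i] ** 2 * (1.0 - q[i]) / D[i]
            weight = (1.0 - a[i]) * n[i] + e[i + 1]
            comps[i] = l[i] ** 2 * weight**2 * s2_q / l0**2
    comps[w] = (l[w] / l0) ** 2 / (m[w] ** 2 * D[w])
    table.variance_components = comps
    table.var_e0 = float(comps.sum())
    table.se = float(np.sqrt(table.var_e0))
    return table


def confidence_interval(e0: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI: e0 +/- z * se at the given level."""
    if se < 0:
        raise DataError("se must be nonnegative")
    if not (0.0 < level < 1.0):
        raise DataError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return e0 - z * se, e0 + z * se


def compute_life_table(
    counts: UnitCounts,
    scheme: AgeBandScheme,
    radix: float = DEFAULT_RADIX,
    ci_level: float = 0.95,
) -> LifeTableResult:
    """Full chain: rates -> probabilities -> table -> variance -> CI.

    Raises FinalBandError when the terminal band has no deaths or
    exposure, and ZeroExposureDeathsError on inconsistent cells.
    """
    m, rate_flags = central_death_rates(counts, scheme)
    q, q_flags = death_probabilities(m, scheme)
    table = build_life_table(q, m, scheme, radix=radix, unit_id=counts.unit_id)
    adjusted_variance(table, counts.deaths, scheme)
    table.ci_level = ci_level
    table.ci_low, table.ci_high = confidence_interval(table.e0, table.se, ci_level)
    table.flags |= rate_flags | q_flags
    return table
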