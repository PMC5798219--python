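"""Reliability screening for small-area life-expectancy estimates.

Small-area LE practice distinguishes two kinds of withholding:

* **exclusion** — the unit should never be estimated (no resident
  population, or a majority group-quarters population such as a prison,
  nursing home or dormitory that distorts the age structure);
* **suppression** — an estimate was computed but is statistically
  unreliable (SE too large, too few person-years or deaths, or an
  implausibly low LE).

All threshold comparisons are strict in the quoted direction: SE
*greater than* se_max, person-years *less than* min_pyar, etc. —
boundary values pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .errors import DataError
from .life_table import LifeTableResult, UnitCounts

__all__ = [
    "RuleSet",
    "Reason",
    "AssessedEstimate",
    "evaluate_exclusions",
    "evaluate_suppression",
    "summarize_flags",
]

log = logging.getLogger(__name__)


class Reason(str, Enum):
    """Reason codes for exclusion / suppression flags."""

    SE_GT_MAX = "SE_GT_MAX"
    PYAR_LT_MIN = "PYAR_LT_MIN"
    DEATHS_LT_MIN = "DEATHS_LT_MIN"
    LE_BELOW_FLOOR = "LE_BELOW_FLOOR"
    GQ_EXCLUDED = "GQ_EXCLUDED"
    ZERO_POPULATION = "ZERO_POPULATION"
    FINAL_BAND_NO_DEATHS = "FINAL_BAND_NO_DEATHS"
    ZERO_EXPOSURE = "ZERO_EXPOSURE"
    UNMERGEABLE = "UNMERGEABLE"

    def __str__(self) -> str:  # clean CSV rendering
        return self.value


EXCLUSION_REASONS = {Reason.GQ_EXCLUDED, Reason.ZERO_POPULATION}


@dataclass(frozen=True)
class RuleSet:
    """Thresholds for reliability screening.

    ``min_deaths``, ``le_floor`` and ``min_population_single_year`` are
    optional rules, disabled when ``None``.  Defaults mirror common
    small-area practice: suppress when SE exceeds 2 years or exposure
    falls below 5,000 person-years; exclude when over half the
    population lives in group quarters.
    """

    se_max: float = 2.0
    min_pyar: float = 5_000.0
    min_deaths: float | None = None  # 60 when enabled
    le_floor: float | None = None  # 66 when enabled
    gq_max: float = 0.5
    min_population_single_year: float | None = None  # 15,000 when enabled

    def __post_init__(self) -> None:
        for name in ("se_max", "min_pyar", "min_deaths", "le_floor", "gq_max",
                     "min_population_single_year"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DataError(f"rule threshold {name} must be nonnegative")


@dataclass
class AssessedEstimate:
    """A life-table result joined with its reliability assessment.

    ``result`` is None when the estimate was non-computable (e.g. no
    deaths in the terminal band).  ``status`` is one of ``reliable``,
    ``suppressed``, ``excluded``.
    """

    unit_id: str
    result: LifeTableResult | None
    flags: set[Reason] = field(default_factory=set)
    status: str = "reliable"
    total_pyar: float = 0.0
    total_deaths: float = 0.0
    members: tuple[str, ...] = ()

    @property
    def reliable(self) -> bool:
        return self.status == "reliable"


def _assign_status(flags: set[Reason]) -> str:
    if flags & EXCLUSION_REASONS:
        return "excluded"
    if flags:
        return "suppressed"
    return "reliable"


def evaluate_exclusions(counts: UnitCounts, rules: RuleSet) -> set[Reason]:
    """Pre-estimation exclusion flags for one unit."""
    flags: set[Reason] = set()
    if counts.gq_fraction is None:
        log.info("unit %s: gq_fraction missing; group-quarters rule skipped",
                 counts.unit_id)
    elif counts.gq_fraction > rules.gq_max:
        flags.add(Reason.GQ_EXCLUDED)
    if counts.total_person_years == 0:
        flags.add(Reason.ZERO_POPULATION)
    return flags


def evaluate_suppression(
    est: AssessedEstimate, rules: RuleSet, annual_population: float | None = None
) -> AssessedEstimate:
    """Apply suppression rules and assign final status.

    Exclusion flags must already be present on ``est``; suppression
    flags are added, and status is derived from the combined set.
    ``annual_population`` feeds the optional single-year minimum-
    population rule.
    """
    flags = set(est.flags)
    if est.result is not None:
        if est.result.se > rules.se_max:
            flags.add(Reason.SE_GT_MAX)
        if rules.le_floor is not None and est.result.e0 < rules.le_floor:
            flags.add(Reason.LE_BELOW_FLOOR)
    if est.total_pyar < rules.min_pyar:
        flags.add(Reason.PYAR_LT_MIN)
    if rules.min_deaths is not None and est.total_deaths < rules.min_deaths:
        flags.add(Reason.DEATHS_LT_MIN)
    if (
        rules.min_population_single_year is not None
        and annual_population is not None
        and annual_population < rules.min_population_single_year
    ):
        flags.add(Reason.PYAR_LT_MIN)
    est.flags = flags
    est.status = _assign_status(flags)
    return est


def summarize_flags(estimates: list[AssessedEstimate]) -> dict:
    """Tally statuses and reasons across a collection of estimates.

    The exclusion share is over all units; the suppression share is
    over non-excluded units (the denominator that would actually be
    published).
    """
    if not estimates:
        raise DataError("cannot summarize an empty collection of estimates")
    n = len(estimates)
    by_status = {"reliable": 0, "suppressed": 0, "excluded": 0}
    reason_counts: dict[str, int] = {}
    for est in estimates:
        by_status[est.status] += 1
        for r in est.flags:
            reason_counts[str(r)] = reason_counts.get(str(r), 0) + 1
    n_excluded = by_status["excluded"]
    n_assessable = n - n_excluded
    return {
        "n_units": n,
        "by_status": by_status,
        "reason_counts": dict(sorted(reason_counts.items())),
        "pct_excluded": 100.0 * n_excluded / n,
        "pct_suppressed": (
            100.0 * by_status["suppressed"] / n_assessable if n_assessable else 0.0
        ),
    }
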