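"""End-to-end pipeline: read counts, pool years, screen, optionally
aggregate, estimate life expectancy, suppress, and summarize
disparities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import io
from .aggregation import MergedRegion, merge_to_thresholds, pool_years
from .bands import default_age_bands
from .config import RunConfig
from .disparity import AssociationResult, compute_ehi, le_gap, le_hardship_association
from .errors import (
    DataError,
    FinalBandError,
    SubcountyLEError,
    ZeroExposureDeathsError,
)
from .life_table import UnitCounts, compute_life_table
from .reliability import (
    AssessedEstimate,
    Reason,
    RuleSet,
    evaluate_exclusions,
    evaluate_suppression,
    summarize_flags,
)

__all__ = ["PipelineResult", "run", "run_pipeline", "assess_units"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    estimates: list[AssessedEstimate]
    summary: dict
    regions: list[MergedRegion] | None = None
    crosswalk: dict[str, str] | None = None
    gap: tuple[float, str, str] | None = None
    association: AssociationResult | None = None


class _Stage:
    """Context manager that prefixes failures with the stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise SubcountyLEError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done", self.name)


def _estimate_one(
    counts: UnitCounts,
    scheme,
    rules: RuleSet,
    ci_level: float,
    prior_flags: set[Reason],
    members: tuple[str, ...] = (),
) -> AssessedEstimate:
    est = AssessedEstimate(
        unit_id=counts.unit_id,
        result=None,
        flags=set(prior_flags),
        total_pyar=counts.total_person_years,
        total_deaths=counts.total_deaths,
        members=members or (counts.unit_id,),
    )
    if est.flags & {Reason.GQ_EXCLUDED, Reason.ZERO_POPULATION}:
        est.status = "excluded"
        return est
    try:
        result = compute_life_table(counts, scheme, ci_level=ci_level)
        est.result = result
        if "ZERO_EXPOSURE" in result.flags:
            est.flags.add(Reason.ZERO_EXPOSURE)
    except FinalBandError:
        est.flags.add(Reason.FINAL_BAND_NO_DEATHS)
    except ZeroExposureDeathsError:
        raise
    annual = (
        counts.total_person_years / counts.years_covered
        if counts.years_covered else None
    )
    return evaluate_suppression(est, rules, annual_population=annual)


def assess_units(
    pooled: list[UnitCounts], scheme, rules: RuleSet, ci_level: float = 0.95
) -> list[AssessedEstimate]:
    """Life table + variance + suppression assessment for each unit."""
    out = []
    for counts in pooled:
        flags = evaluate_exclusions(counts, rules)
        out.append(_estimate_one(counts, scheme, rules, ci_level, flags))
    return out


def run(cfg: RunConfig) -> PipelineResult:
    """Execute the pipeline and return in-memory results.

    Raises SubcountyLEError naming the failing stage on any error.
    """
    scheme = default_age_bands(cfg.scheme)
    rules = cfg.rules()

    with _Stage("read"):
        if not cfg.deaths or not cfg.population:
            raise DataError("deaths and population paths are required")
        yearly = io.read_counts(cfg.deaths, cfg.population, scheme)
        gq = io.read_gq_fractions(cfg.gq) if cfg.gq else None
        indicators = io.read_indicators(cfg.indicators) if cfg.indicators else None
        graph = None
        if cfg.adjacency:
            graph = io.read_adjacency(cfg.adjacency, {c.unit_id for c in yearly})
        log.info("read %d unit-year records", len(yearly))

    with _Stage("pool_years"):
        if cfg.years is not None:
            keep = sorted({c.year for c in yearly})[: cfg.years]
            yearly = [c for c in yearly if c.year in keep]
        by_unit: dict[str, list[UnitCounts]] = {}
        for c in yearly:
            by_unit.setdefault(c.unit_id, []).append(c)
        pooled = [pool_years(records) for records in by_unit.values()]
        if gq is not None:
            for counts in pooled:
                if counts.unit_id in gq.index:
                    counts.gq_fraction = float(gq[counts.unit_id])
        log.info("pooled %d unit-years into %d units", len(yearly), len(pooled))

    with _Stage("evaluate_exclusions"):
        exclusion_flags = {c.unit_id: evaluate_exclusions(c, rules) for c in pooled}
        excluded = [u for u, f in exclusion_flags.items() if f]
        log.info("%d of %d units excluded up front", len(excluded), len(pooled))

    regions = crosswalk = None
    estimates: list[AssessedEstimate] = []
    if cfg.aggregate:
        with _Stage("merge_to_thresholds"):
            if graph is None:
                raise DataError("aggregation requires an adjacency file")
            mergeable = [c for c in pooled if not exclusion_flags[c.unit_id]]
            regions, crosswalk = merge_to_thresholds(
                mergeable, graph, rules, tuple(cfg.aggregate_criteria), scheme=scheme
            )
            log.info("merged %d units into %d regions", len(mergeable), len(regions))

    with _Stage("estimate"):
        if regions is not None:
            for c in pooled:
                if exclusion_flags[c.unit_id]:
                    estimates.append(
                        _estimate_one(c, scheme, rules, cfg.ci_level,
                                      exclusion_flags[c.unit_id])
                    )
            for region in regions:
                prior = {Reason.UNMERGEABLE} if region.unmergeable else set()
                estimates.append(
                    _estimate_one(
                        region.counts, scheme, rules, cfg.ci_level, prior,
                        members=tuple(sorted(region.members)),
                    )
                )
        else:
            estimates = assess_units(pooled, scheme, rules, cfg.ci_level)
        log.info("estimated %d units/regions", len(estimates))

    with _Stage("disparity"):
        summary = summarize_flags(estimates)
        gap = association = None
        reliable = [e for e in estimates if e.reliable]
        if len(reliable) >= 2:
            gap = le_gap(estimates)
        if indicators is not None and len(reliable) >= 3:
            import pandas as pd

            ehi = compute_ehi(indicators)
            le = pd.Series(
                {e.unit_id: e.result.e0 for e in reliable}, name="le"
            )
            common = le.index.intersection(ehi.index)
            if len(common) >= 3:
                association = le_hardship_association(le[common], ehi[common])

    with _Stage("write"):
        io.write_results(estimates, cfg.out, show_suppressed=cfg.show_suppressed)
        if crosswalk is not None:
            io.write_crosswalk(crosswalk, cfg.out)
        io.write_summary(_render_summary(summary, gap, association), cfg.out)

    return PipelineResult(
        estimates=estimates, summary=summary, regions=regions,
        crosswalk=crosswalk, gap=gap, association=association,
    )


def _render_summary(summary: dict, gap, association) -> str:
    lines = [
        f"units assessed: {summary['n_units']}",
        f"reliable: {summary['by_status']['reliable']}",
        f"suppressed: {summary['by_status']['suppressed']}"
        f" ({summary['pct_suppressed']:.1f}% of non-excluded)",
        f"excluded: {summary['by_status']['excluded']}"
        f" ({summary['pct_excluded']:.1f}% of all units)",
    ]
    if summary["reason_counts"]:
        lines.append("flag counts: " + ", ".join(
            f"{k}={v}" for k, v in summary["reason_counts"].items()))
    if gap is not None:
        g, lo, hi = gap
        lines.append(f"LE gap (reliable units): {g:.1f} years ({lo} to {hi})")
    if association is not None and not association.degenerate:
        lines.append(
            f"LE-hardship association ({association.method}, n={association.n}): "
            f"{association.coefficient:.3f}"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> int:
    """CLI-facing wrapper: 0 on success, 1 on any stage failure."""
    try:
        run(cfg)
    except SubcountyLEError as exc:
        log.error("%s", exc)
        return 1
    return 0
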