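"""Temporal pooling and greedy geographic aggregation.

Pooling years of data multiplies person-years-at-risk, shrinking the
standard error of e0 roughly as 1/sqrt(years).  When pooling is not
enough, adjacent small areas are merged until every resulting region
meets the reliability criteria — the strategy health departments apply
with regionalization tools when single tracts cannot support a
reliable estimate.

The merge heuristic is deterministic: repeatedly take the failing
region with the fewest total deaths (ties broken by fewer person-years,
then lexicographically smallest member id) and merge it into its
neighboring region with the fewest total deaths (same tie-break).
Failing regions with no neighbors — islands, or whole connected
components that still fail — are flagged unmergeable and withdrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .bands import AgeBandScheme
from .errors import DataError, LifeTableError
from .life_table import UnitCounts, compute_life_table
from .reliability import RuleSet

__all__ = ["MergedRegion", "pool_years", "merge_to_thresholds", "grid_adjacency"]

MERGE_CRITERIA = ("min_deaths", "se_max", "min_pyar")


@dataclass
class MergedRegion:
    """A connected group of units with band-wise pooled counts."""

    region_id: str
    members: frozenset[str]
    counts: UnitCounts
    pass_status: bool = False
    unmergeable: bool = False


def pool_years(yearly: list[UnitCounts]) -> UnitCounts:
    """Sum deaths and person-years across years for one unit."""
    if not yearly:
        raise DataError("pool_years requires at least one record")
    unit_ids = {c.unit_id for c in yearly}
    if len(unit_ids) > 1:
        raise DataError(f"pool_years got records for several units: {sorted(unit_ids)}")
    years = [c.year for c in yearly]
    if None not in years and len(set(years)) < len(years):
        raise DataError(f"unit {yearly[0].unit_id!r}: duplicate (unit, year) records")
    return UnitCounts(
        unit_id=yearly[0].unit_id,
        deaths=np.sum([c.deaths for c in yearly], axis=0),
        person_years=np.sum([c.person_years for c in yearly], axis=0),
        years_covered=len(yearly),
        gq_fraction=yearly[0].gq_fraction,
    )


def _pool_units(members: list[UnitCounts], region_id: str) -> UnitCounts:
    gq = [c.gq_fraction for c in members if c.gq_fraction is not None]
    pys = np.array([c.total_person_years for c in members])
    # population-weighted group-quarters share for the pooled region
    gq_fraction = None
    if len(gq) == len(members) and pys.sum() > 0:
        gq_fraction = float(np.average(gq, weights=pys)) if pys.sum() else None
    return UnitCounts(
        unit_id=region_id,
        deaths=np.sum([c.deaths for c in members], axis=0),
        person_years=np.sum([c.person_years for c in members], axis=0),
        years_covered=members[0].years_covered,
        gq_fraction=gq_fraction,
    )


def _region_passes(
    counts: UnitCounts, scheme: AgeBandScheme, rules: RuleSet, criteria: tuple[str, ...]
) -> bool:
    if "min_deaths" in criteria and counts.total_deaths < (rules.min_deaths or 60.0):
        return False
    if "min_pyar" in criteria and counts.total_person_years < rules.min_pyar:
        return False
    if "se_max" in criteria:
        try:
            table = compute_life_table(counts, scheme)
        except LifeTableError:
            return False
        if table.se > rules.se_max:
            return False
    return True


def _sort_key(members: frozenset[str], by_unit: dict[str, UnitCounts]):
    deaths = sum(by_unit[u].total_deaths for u in members)
    pyar = sum(by_unit[u].total_person_years for u in members)
    return (deaths, pyar, min(members))


def merge_to_thresholds(
    units: list[UnitCounts],
    graph: nx.Graph,
    rules: RuleSet,
    criteria: tuple[str, ...] = ("min_deaths",),
    scheme: AgeBandScheme | None = None,
) -> tuple[list[MergedRegion], dict[str, str]]:
    """Greedily merge adjacent units until all regions pass ``criteria``.

    Returns the regions (a partition of the input units) and a
    crosswalk mapping each unit_id to its region_id.  Region ids are
    the unit id itself for singleton regions and "R" + the
    lexicographically smallest member id otherwise.
    """
    if not units:
        raise DataError("merge_to_thresholds requires at least one unit")
    if not criteria:
        raise DataError("at least one merge criterion is required")
    unknown = set(criteria) - set(MERGE_CRITERIA)
    if unknown:
        raise DataError(f"unknown merge criteria: {sorted(unknown)}")
    if "se_max" in criteria and scheme is None:
        raise DataError("se_max criterion requires an age-band scheme")
    by_unit = {c.unit_id: c for c in units}
    if len(by_unit) != len(units):
        raise DataError("duplicate unit ids in merge input")
    missing = set(by_unit) - set(graph.nodes)
    if missing:
        raise DataError(f"units missing from adjacency graph: {sorted(missing)[:5]}")
    graph = graph.subgraph(by_unit.keys())

    def region_counts(members: frozenset[str]) -> UnitCounts:
        rid = min(members) if len(members) == 1 else "R" + min(members)
        return _pool_units([by_unit[u] for u in sorted(members)], rid)

    def passes(members: frozenset[str]) -> bool:
        return _region_passes(region_counts(members), scheme, rules, tuple(criteria))

    regions: list[frozenset[str]] = [frozenset([u]) for u in by_unit]
    status = {r: passes(r) for r in regions}
    withdrawn: set[frozenset[str]] = set()

    while True:
        failing = [r for r in regions if not status[r] and r not in withdrawn]
        if not failing:
            break
        target = min(failing, key=lambda r: _sort_key(r, by_unit))
        member_of = {u: r for r in regions for u in r}
        neighbor_regions = {
            member_of[v]
            for u in target
            for v in graph.neighbors(u)
            if member_of[v] is not target
        }
        if not neighbor_regions:
            withdrawn.add(target)
            continue
        partner = min(neighbor_regions, key=lambda r: _sort_key(r, by_unit))
        merged = target | partner
        regions = [r for r in regions if r is not target and r is not partner]
        regions.append(merged)
        for r in (target, partner):
            status.pop(r)
            withdrawn.discard(r)
        status[merged] = passes(merged)

    result: list[MergedRegion] = []
    crosswalk: dict[str, str] = {}
    for members in sorted(regions, key=min):
        counts = region_counts(members)
        result.append(
            MergedRegion(
                region_id=counts.unit_id,
                members=members,
                counts=counts,
                pass_status=status[members],
                unmergeable=members in withdrawn,
            )
        )
        for u in members:
            crosswalk[u] = counts.unit_id
    return result, crosswalk


def grid_adjacency(nrows: int, ncols: int, ids: list[str]) -> nx.Graph:
    """4-neighbor (rook) adjacency for units laid out on a grid,
    row-major in ``ids``."""
    if len(ids) != nrows * ncols:
        raise DataError("grid dimensions do not match the number of unit ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for r in range(nrows):
        for c in range(ncols):
            u = ids[r * ncols + c]
            if c + 1 < ncols:
                g.add_edge(u, ids[r * ncols + c + 1])
            if r + 1 < nrows:
                g.add_edge(u, ids[(r + 1) * ncols + c])
    return g
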