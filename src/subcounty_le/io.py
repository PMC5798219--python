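"""CSV readers and writers.

All interchange is plain CSV with opaque unit ids, so 11-character
tract FIPS codes, minor-civil-division codes and ZIP codes all work
unchanged.  Counts come as long-format tables with columns
``unit_id, year, age_band, count``; age-band labels must match the
scheme's label dialect ("0", "1-4", "5-9", ..., "85+") exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .aggregation import MergedRegion
from .bands import AgeBandScheme
from .errors import DataError
from .life_table import UnitCounts
from .reliability import AssessedEstimate

__all__ = [
    "read_counts",
    "read_adjacency",
    "read_gq_fractions",
    "read_indicators",
    "write_results",
    "write_crosswalk",
    "write_study",
]

log = logging.getLogger(__name__)

COUNT_COLUMNS = ["unit_id", "year", "age_band", "count"]


def _read_count_table(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str, "age_band": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{what} file {path}: missing columns {sorted(missing)}")
    if df["count"].isna().any() or (df["count"] < 0).any():
        bad = df.index[df["count"].isna() | (df["count"] < 0)][0]
        raise DataError(f"{what} file {path}: negative or missing count at row {bad + 2}")
    dups = df.duplicated(subset=["unit_id", "year", "age_band"])
    if dups.any():
        row = df.index[dups][0]
        raise DataError(f"{what} file {path}: duplicate (unit, year, band) at row {row + 2}")
    return df


def _check_labels(df: pd.DataFrame, scheme: AgeBandScheme, path, what: str) -> None:
    known = set(scheme.labels)
    bad = ~df["age_band"].isin(known)
    if bad.any():
        row = df.index[bad][0]
        raise DataError(
            f"{what} file {path}: unknown age-band label "
            f"{df.loc[row, 'age_band']!r} at row {row + 2} "
            f"(scheme {scheme.name!r})"
        )


def read_counts(
    deaths_path: str | Path, population_path: str | Path, scheme: AgeBandScheme
) -> list[UnitCounts]:
    """Read deaths and population CSVs into per-(unit, year) counts.

    Population rows must cover every (unit, year, band) cell; missing
    death rows default to zero deaths with a logged notice.  The
    population count for a unit-year is taken as that year's
    person-years of exposure.
    """
    deaths = _read_count_table(deaths_path, "deaths")
    pop = _read_count_table(population_path, "population")
    _check_labels(deaths, scheme, deaths_path, "deaths")
    _check_labels(pop, scheme, population_path, "population")

    labels = scheme.labels
    pop_piv = pop.pivot_table(
        index=["unit_id", "year"], columns="age_band", values="count", dropna=False
    )
    if pop_piv.isna().any().any() or set(labels) - set(pop_piv.columns):
        raise DataError(
            f"population file {population_path}: every (unit, year) must "
            "have a row for every age band"
        )
    pop_piv = pop_piv[labels]

    death_piv = deaths.pivot_table(
        index=["unit_id", "year"], columns="age_band", values="count", dropna=False
    ).reindex(index=pop_piv.index, columns=labels)
    n_missing = int(death_piv.isna().sum().sum())
    if n_missing:
        log.info("deaths file: %d absent (unit, year, band) rows treated as 0 deaths",
                 n_missing)
    death_piv = death_piv.fillna(0.0)

    extra = set(death_piv.index) - set(pop_piv.index)
    if extra:
        raise DataError(f"deaths present for unit-years without population: {sorted(extra)[:5]}")

    records = []
    for (unit_id, year), prow in pop_piv.iterrows():
        records.append(
            UnitCounts(
                unit_id=str(unit_id),
                deaths=death_piv.loc[(unit_id, year)].to_numpy(),
                person_years=prow.to_numpy(),
                years_covered=1,
                year=int(year),
            )
        )
    return records


def read_adjacency(path: str | Path, known_units: set[str] | None = None) -> nx.Graph:
    """Undirected edge list CSV (two columns of unit ids)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"adjacency file {path}: expected two columns")
    g = nx.Graph()
    if known_units is not None:
        g.add_nodes_from(known_units)
    for _, (u, v) in df.iloc[:, :2].iterrows():
        if u == v:
            raise DataError(f"adjacency file {path}: self-loop at unit {u!r}")
        if known_units is not None and (u not in known_units or v not in known_units):
            raise DataError(f"adjacency file {path}: edge references unknown unit {u!r}-{v!r}")
        g.add_edge(u, v)
    return g


def read_gq_fractions(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={"unit_id": str})
    if not {"unit_id", "gq_fraction"} <= set(df.columns):
        raise DataError(f"group-quarters file {path}: need columns unit_id, gq_fraction")
    s = df.set_index("unit_id")["gq_fraction"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise DataError(f"group-quarters file {path}: fractions must lie in [0, 1]")
    return s


def read_indicators(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    if "unit_id" not in df.columns:
        raise DataError(f"indicators file {path}: need a unit_id column")
    return df.set_index("unit_id")


def _fmt(x: float | None) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6f}"


def write_results(
    estimates: list[AssessedEstimate],
    out_dir: str | Path,
    show_suppressed: bool = False,
) -> Path:
    """Write results.csv; non-reliable rows keep their flags but have
    e0/se/CI blanked unless ``show_suppressed`` is set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for est in sorted(estimates, key=lambda e: e.unit_id):
        show = est.reliable or show_suppressed
        res = est.result
        rows.append(
            {
                "unit_or_region_id": est.unit_id,
                "members": ";".join(sorted(est.members)) if est.members else est.unit_id,
                "pyar": f"{est.total_pyar:.2f}",
                "deaths": f"{est.total_deaths:g}",
                "e0": _fmt(res.e0) if res is not None and show else "",
                "se": _fmt(res.se) if res is not None and show else "",
                "ci_low": _fmt(res.ci_low) if res is not None and show else "",
                "ci_high": _fmt(res.ci_high) if res is not None and show else "",
                "status": est.status,
                "flags": ";".join(sorted(str(f) for f in est.flags)),
            }
        )
    path = out_dir / "results.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_crosswalk(crosswalk: dict[str, str], out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "crosswalk.csv"
    pd.DataFrame(
        sorted(crosswalk.items()), columns=["unit_id", "region_id"]
    ).to_csv(path, index=False)
    return path


def write_summary(summary_text: str, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "summary.txt"
    path.write_text(summary_text)
    return path


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study in the same CSV formats the pipeline
    reads, plus a truth table (unit_id, true_e0, hazard_ratio,
    hardship)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = [b.label for b in study.schedules[study.unit_ids[0]].scheme]

    death_rows, pop_rows = [], []
    for c in study.counts:
        for label, d, p in zip(labels, c.deaths, c.person_years):
            pop_rows.append((c.unit_id, c.year, label, p))
            if d > 0:
                death_rows.append((c.unit_id, c.year, label, int(d)))
    paths = {}
    paths["deaths"] = out_dir / "deaths.csv"
    pd.DataFrame(death_rows, columns=COUNT_COLUMNS).to_csv(paths["deaths"], index=False)
    paths["population"] = out_dir / "population.csv"
    pd.DataFrame(pop_rows, columns=COUNT_COLUMNS).to_csv(paths["population"], index=False)
    paths["adjacency"] = out_dir / "adjacency.csv"
    pd.DataFrame(sorted(study.adjacency.edges), columns=["unit_a", "unit_b"]).to_csv(
        paths["adjacency"], index=False
    )
    paths["gq"] = out_dir / "gq.csv"
    study.gq_fractions.round(6).reset_index().to_csv(paths["gq"], index=False)
    paths["indicators"] = out_dir / "indicators.csv"
    study.indicators.round(4).reset_index().to_csv(paths["indicators"], index=False)
    paths["truth"] = out_dir / "truth.csv"
    study.truth.round(6).reset_index().to_csv(paths["truth"], index=False)
    return paths
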