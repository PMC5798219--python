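"""Run configuration: YAML file plus command-line overrides.

Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .reliability import RuleSet

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    deaths: str | None = None
    population: str | None = None
    adjacency: str | None = None
    gq: str | None = None
    indicators: str | None = None
    out: str = "results"
    scheme: str = "standard_85"
    years: int | None = None  # restrict to the first N calendar years
    se_max: float = 2.0
    min_pyar: float = 5_000.0
    min_deaths: float | None = None
    le_floor: float | None = None
    gq_max: float = 0.5
    min_population_single_year: float | None = None
    ci_level: float = 0.95
    aggregate: bool = False
    aggregate_criteria: tuple[str, ...] = ("min_deaths", "se_max")
    show_suppressed: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def rules(self) -> RuleSet:
        return RuleSet(
            se_max=self.se_max,
            min_pyar=self.min_pyar,
            min_deaths=self.min_deaths,
            le_floor=self.le_floor,
            gq_max=self.gq_max,
            min_population_single_year=self.min_population_single_year,
        )


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Override values of ``None`` are ignored, so CLI flags only take
    effect when explicitly given.  The effective configuration is
    echoed to the log for auditability.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - _FIELDS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    for key, val in overrides.items():
        if key not in _FIELDS:
            raise ConfigurationError(f"unknown config key: {key!r}")
        if val is not None:
            values[key] = val
    if "aggregate_criteria" in values:
        values["aggregate_criteria"] = tuple(values["aggregate_criteria"])
    cfg = RunConfig(**values)
    log.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
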