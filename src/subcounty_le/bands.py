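"""Abridged age-band schemes for life-table construction.

An abridged life table groups ages into intervals — conventionally an
infant band [0,1), a childhood band [1,5), 5-year bands, and an
open-ended terminal band (85+ or 90+).  Each closed band carries a
"fraction of interval lived" a_i: the average share of the interval
lived by those who die within it (0.1 for infants, whose deaths cluster
near birth; 0.5 elsewhere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError

__all__ = ["AgeBand", "AgeBandScheme", "default_age_bands", "SCHEME_NAMES"]

SCHEME_NAMES = ("standard_85", "standard_90", "collapsed_0_4")


@dataclass(frozen=True)
class AgeBand:
    """One age interval of an abridged scheme.

    ``width`` is ``math.inf`` for the final open-ended band.
    """

    index: int
    lower_bound: float
    width: float
    fraction_lived: float
    label: str

    @property
    def is_open(self) -> bool:
        return math.isinf(self.width)

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_lived <= 1.0):
            raise ConfigurationError(
                f"band {self.label!r}: fraction_lived must be in (0, 1], "
                f"got {self.fraction_lived}"
            )
        if self.width <= 0:
            raise ConfigurationError(f"band {self.label!r}: width must be positive")


@dataclass(frozen=True)
class AgeBandScheme:
    """Ordered, contiguous age bands ending in one open-ended band."""

    bands: tuple[AgeBand, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("scheme must contain at least one band")
        if self.bands[0].lower_bound != 0:
            raise ConfigurationError("first band must start at age 0")
        for prev, cur in zip(self.bands, self.bands[1:]):
            if prev.is_open:
                raise ConfigurationError("open-ended band must be last")
            if not math.isclose(prev.lower_bound + prev.width, cur.lower_bound):
                raise ConfigurationError(
                    f"bands {prev.label!r} and {cur.label!r} are not contiguous"
                )
        if not self.bands[-1].is_open:
            raise ConfigurationError("final band must be open-ended")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def final_index(self) -> int:
        """Index w of the open-ended terminal band."""
        return len(self.bands) - 1

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    @property
    def lower_bounds(self) -> list[float]:
        return [b.lower_bound for b in self.bands]

    @property
    def widths(self) -> list[float]:
        return [b.width for b in self.bands]

    @property
    def fractions_lived(self) -> list[float]:
        return [b.fraction_lived for b in self.bands]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown age-band label {label!r}") from None


def _five_year_bands(start_index: int, start_age: int, terminal: int) -> list[AgeBand]:
    bands = []
    i = start_index
    for lo in range(start_age, terminal, 5):
        bands.append(AgeBand(i, float(lo), 5.0, 0.5, f"{lo}-{lo + 4}"))
        i += 1
    bands.append(AgeBand(i, float(terminal), math.inf, 1.0, f"{terminal}+"))
    return bands


def default_age_bands(scheme_name: str = "standard_85") -> AgeBandScheme:
    """Return a named abridged age-band scheme.

    ``standard_85``
        19 bands: [0,1) with a=0.1, [1,5), then 5-year bands up to 85+.
    ``standard_90``
        20 bands, extending the terminal band to 90+.
    ``collapsed_0_4``
        18 bands: the infant and childhood bands merged into [0,5) with
        a=0.5, for data sources that only report a 0–4 category.
    """
    if scheme_name in ("standard_85", "standard_90"):
        terminal = 85 if scheme_name == "standard_85" else 90
        bands = [
            AgeBand(0, 0.0, 1.0, 0.1, "0"),
            AgeBand(1, 1.0, 4.0, 0.5, "1-4"),
        ]
        bands += _five_year_bands(2, 5, terminal)
    elif scheme_name == "collapsed_0_4":
        bands = [AgeBand(0, 0.0, 5.0, 0.5, "0-4")]
        bands += _five_year_bands(1, 5, 85)
    else:
        raise ConfigurationError(
            f"unknown age-band scheme {scheme_name!r}; "
            f"expected one of {SCHEME_NAMES}"
        )
    return AgeBandScheme(tuple(bands), name=scheme_name)
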