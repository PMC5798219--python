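import math

import numpy as np
import pytest

from subcounty_le.bands import AgeBand, AgeBandScheme, default_age_bands
from subcounty_le.life_table import UnitCounts
from subcounty_le.synthetic import SyntheticConfig, generate_study, gompertz_makeham_schedule


@pytest.fixture(scope="session")
def std_scheme():
    return default_age_bands("standard_85")


@pytest.fixture(scope="session")
def toy_scheme():
    """Three-band scheme used for hand-evaluated fixtures:
    [0,1) a=0.1, [1,5) a=0.5, open 5+."""
    return AgeBandScheme(
        (
            AgeBand(0, 0.0, 1.0, 0.1, "0"),
            AgeBand(1, 1.0, 4.0, 0.5, "1-4"),
            AgeBand(2, 5.0, math.inf, 1.0, "5+"),
        ),
        name="toy3",
    )


@pytest.fixture()
def toy_counts(toy_scheme):
    """Counts whose rates are m = (0.01, 0.002, 0.02)."""
    return UnitCounts(
        unit_id="toy",
        deaths=np.array([100.0, 80.0, 2000.0]),
        person_years=np.array([10_000.0, 40_000.0, 100_000.0]),
    )


@pytest.fixture(scope="session")
def baseline_schedule(std_scheme):
    return gompertz_makeham_schedule(scheme=std_scheme)


@pytest.fixture(scope="session")
def small_study():
    """A 6x6 synthetic study shared by interface/disparity tests."""
    return generate_study(SyntheticConfig(grid_rows=6, grid_cols=6, seed=11))


@pytest.fixture(scope="session")
def default_study():
    """The full default 400-unit study at a fixed seed."""
    return generate_study(SyntheticConfig(seed=2026))
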