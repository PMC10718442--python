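import numpy as np
import pytest

from crashhawkes import (HawkesModel, StationaryBackground, TriggeringParams)
from crashhawkes.simulate import simulate_branching

#: Ground-truth stationary model used across the recovery/decluster tests.
TRUE_MU, TRUE_A, TRUE_ALPHA = 0.4, 0.25, 12.0


@pytest.fixture(scope="session")
def stationary_truth():
    return HawkesModel(StationaryBackground(TRUE_MU),
                       TriggeringParams(TRUE_A, TRUE_ALPHA))


@pytest.fixture(scope="session")
def sim_small(stationary_truth):
    """~300-event simulated catalog with ground-truth parents (T=500 d)."""
    return simulate_branching(stationary_truth, 500.0, seed=42)


@pytest.fixture(scope="session")
def sim_large(stationary_truth):
    """~1100-event simulated catalog (T=2000 d) for fitting tests."""
    return simulate_branching(stationary_truth, 2000.0, seed=7)


FIXTURE_ROWS = [
    # (date, time, lon, lat) — hand-convertible timestamps (origin 2015-03-02)
    ("2015-03-02", "00:00", -81.30, 28.50),
    ("2015-03-02", "06:30", -81.31, 28.51),
    ("2015-03-02", "12:00", -81.32, 28.52),
    ("2015-03-03", "00:00", -81.33, 28.53),
    ("2015-03-03", "18:45", -81.34, 28.54),
    ("2015-03-05", "03:15", -81.35, 28.55),
    ("2015-03-08", "23:59", -81.36, 28.56),
    ("2015-03-10", "07:05", -81.37, 28.57),
    ("2015-03-14", "16:20", -81.38, 28.58),
    ("2015-03-15", "09:10", -81.39, 28.59),
]

#: Day offsets of FIXTURE_ROWS computed by hand: whole days since 2015-03-02
#: plus minutes-past-midnight / 1440.
FIXTURE_T_DAYS = [
    0.0,
    390 / 1440,
    720 / 1440,
    1.0,
    1.0 + 1125 / 1440,
    3.0 + 195 / 1440,
    6.0 + 1439 / 1440,
    8.0 + 425 / 1440,
    12.0 + 980 / 1440,
    13.0 + 550 / 1440,
]


@pytest.fixture()
def fixture_csv(tmp_path):
    path = tmp_path / "events.csv"
    lines = ["crash_date,crash_time,longitude,latitude,weather"]
    for d, t, lon, lat in FIXTURE_ROWS:
        lines.append(f"{d},{t},{lon},{lat},clear")
    path.write_text("\n".join(lines) + "\n")
    return path
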