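import datetime

import numpy as np
import pytest

from daytrace.core import DayMatrix

START = datetime.date(2008, 1, 7)


def make_matrix(rows, user="u0", start=START):
    """Build a DayMatrix from a list of per-day label lists."""
    rows = [list(r) for r in rows]
    dates = [start + datetime.timedelta(days=i) for i in range(len(rows))]
    return DayMatrix(user, dates, np.array(rows, dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_pattern_matrix():
    """10 complete days alternating two internally constant patterns."""
    day_a = ["H"] * 9 + ["W"] * 8 + ["H"] * 7
    day_b = ["H"] * 10 + ["S"] * 6 + ["H"] * 8
    return make_matrix([day_a, day_b] * 5)


@pytest.fixture(scope="session")
def planted_config():
    """Shared planted-recovery generator config (no gaps, no work jitter)."""
    from daytrace.synthetic import GapSpec, GeneratorConfig

    return GeneratorConfig(
        n_users=1,
        n_days=120,
        n_locations=40,
        templates_per_user=3,
        noise_rate=0.05,
        seed=11,
        departure_params=None,
        gap_spec=GapSpec(night_prob=0.0, random_rate=0.0),
    )
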