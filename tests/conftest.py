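import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # oracles / published_values

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from apcie import RateTable, AgeGroup, PeriodBin  # noqa: E402
from apcie.synthetic import make_spec, simulate_counts  # noqa: E402


@pytest.fixture
def small_table() -> RateTable:
    """Deterministic 4x3 table with mixed counts, including a zero cell."""
    rng = np.random.default_rng(42)
    deaths = rng.poisson(30.0, size=(4, 3)).astype(float)
    deaths[0, 0] = 0.0
    return RateTable(
        country="synthetic",
        cancer="synthetic",
        age_groups=[AgeGroup(20 + 5 * i) for i in range(4)],
        period_bins=[PeriodBin(1999 + 5 * j) for j in range(3)],
        deaths=deaths,
        person_years=np.full((4, 3), 2e5),
    )


@pytest.fixture
def default_spec():
    return make_spec(seed=0)


@pytest.fixture
def default_fit(default_spec):
    from apcie import fit_ie

    return fit_ie(simulate_counts(default_spec))
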