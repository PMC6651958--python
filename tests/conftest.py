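import pandas as pd
import pytest

from smokesim.ages import BANDS
from smokesim.fixtures import default_rate_tables
from smokesim.mortality import MortalitySchedule, RelativeRiskTable
from smokesim.rates import build_rate_schedule


@pytest.fixture(scope="session")
def fixture_schedule():
    """Rate schedule built from the packaged 2014 male tables, relapse 0.03."""
    cess, init = default_rate_tables("male")
    return build_rate_schedule(cess, init, relapse=0.03, sex="male")


@pytest.fixture
def flat_mortality():
    """Constant all-cause rate 0.01 for males, 2015-2025."""
    rows = [
        {"year": y, "sex": "male", "age_group": b, "all_cause_rate": 0.01}
        for y in range(2015, 2026)
        for b in BANDS
    ]
    return MortalitySchedule(pd.DataFrame(rows))


@pytest.fixture
def zero_mortality():
    rows = [
        {"year": y, "sex": "male", "age_group": b, "all_cause_rate": 0.0}
        for y in range(2015, 2026)
        for b in BANDS
    ]
    return MortalitySchedule(pd.DataFrame(rows))


@pytest.fixture
def unit_rr():
    return RelativeRiskTable.uniform(1.0, 1.0, sexes=("male",))


@pytest.fixture
def uniform_entrants():
    return {y: 0.0 for y in range(2015, 2026)}


def uniform_schedule(initiation=0.0, cessation=0.0, relapse=0.0):
    """A schedule with the same rates at every age (helper, not a fixture)."""
    init = {b: initiation for b in BANDS}
    cess = {b: cessation for b in BANDS}
    return build_rate_schedule(cess, init, relapse=relapse, sex="male")
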