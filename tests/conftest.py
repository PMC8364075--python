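import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the microsim oracle module

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from petcea import (
    current_practice,
    default_parameters,
    pet_strategy,
    synthetic_life_table,
)


@pytest.fixture(scope="session")
def params():
    """Base-case parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    """Synthetic Gompertz fixture life table covering ages 60-120."""
    return synthetic_life_table()


@pytest.fixture(scope="session")
def strat_current(params):
    return current_practice(params)


@pytest.fixture(scope="session")
def strat_pet(params):
    return pet_strategy(params)
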