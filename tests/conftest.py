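import numpy as np
import pytest

from scidcea import (
    LifeTable,
    ParameterSet,
    default_life_table,
    run_strategy,
)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return default_life_table()


@pytest.fixture(scope="session")
def zero_mortality() -> LifeTable:
    """Immortal background population, for closed-form checks."""
    return LifeTable(q=np.zeros(101), label="zero")


@pytest.fixture(scope="session")
def cohorts_5y(params, life_table):
    """Default early/late cohort results over 5 years (computed once)."""
    return {
        arm: run_strategy(params, life_table, arm, 5) for arm in ("early", "late")
    }


@pytest.fixture(scope="session")
def cohorts_60y(params, life_table):
    return {
        arm: run_strategy(params, life_table, arm, 60) for arm in ("early", "late")
    }
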