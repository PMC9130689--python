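import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import geocna as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_fixture() -> g.CaseTable:
    """Deterministic case table matching the printed cross-classification."""
    return g.build_study_fixture()


@pytest.fixture(scope="session")
def outcome_literal() -> g.Literal:
    return g.Literal("PLOW", [1])


@pytest.fixture
def toy_table() -> g.CaseTable:
    """8-case table where Y=1 exactly when A=1 and B=0."""
    levels = pd.DataFrame(
        {
            "A": [1, 1, 1, 1, 0, 0, 0, 0],
            "B": [0, 0, 1, 2, 0, 1, 2, 0],
            "C": [0, 1, 2, 0, 1, 2, 0, 1],
        },
        index=[f"c{i}" for i in range(8)],
    )
    levels["Y"] = ((levels["A"] == 1) & (levels["B"] == 0)).astype(int)
    return g.CaseTable(levels=levels, outcome_name="Y")


def random_case_table(rng: np.random.Generator,
                      max_factors: int = 5,
                      max_cases: int = 50) -> g.CaseTable:
    """Random small multi-value table with a non-constant binary outcome."""
    n_factors = int(rng.integers(2, max_factors + 1))
    n_cases = int(rng.integers(6, max_cases + 1))
    names = [chr(ord("A") + i) for i in range(n_factors)]
    while True:
        levels = pd.DataFrame(
            {f: rng.integers(0, int(rng.integers(2, 4)), size=n_cases)
             for f in names},
            index=[f"c{i}" for i in range(n_cases)],
        )
        levels["Y"] = rng.integers(0, 2, size=n_cases)
        if 0 < levels["Y"].sum() < n_cases:
            return g.CaseTable(levels=levels.astype(int), outcome_name="Y")
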