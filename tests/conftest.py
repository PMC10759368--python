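import numpy as np
import pandas as pd
import pytest

import cogscreen as cs


@pytest.fixture(scope="session")
def norms():
    return cs.default_norms()


@pytest.fixture(scope="session")
def population():
    """Default-condition synthetic population, n=1000, fixed seed."""
    return cs.generate_population(cs.SimulationConfig(n_participants=1000, seed=42))


@pytest.fixture(scope="session")
def labeled(population, norms):
    return cs.classify_records(population, norms)


@pytest.fixture(scope="session")
def scored(labeled):
    return cs.score_records(labeled)


@pytest.fixture(scope="session")
def analyzable(scored):
    """Scored population with excluded records dropped."""
    return scored[scored["impairment"] != "excluded"].reset_index(drop=True)


def make_records(**columns) -> pd.DataFrame:
    """Minimal hand-built record frame with schema defaults filled in."""
    n = max(len(np.atleast_1d(v)) for v in columns.values())
    base = {
        "participant_id": [f"H{i:04d}" for i in range(n)],
        "age": 72.0,
        "sex": "female",
        "education_years": 16.0,
        "race": "White",
        "ethnicity": "Non-Hispanic",
        "ravlt_long_delay": 9.0,
        "tmtb_seconds": 110.0,
        "faq": 0,
        "mmse": 29,
        "dct_summary": 80.0,
        "delayed_recall": 3,
    }
    base.update(columns)
    return pd.DataFrame(base)
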