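import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_records(rows):
    """Build a respondent table from (county, state, age, sex, race, y, w) tuples."""
    return pd.DataFrame(
        rows, columns=["county", "state", "age", "sex", "race", "outcome", "weight"]
    )


@pytest.fixture
def small_records():
    """Five clean interviews across two counties in one state."""
    return make_records(
        [
            ("A", "S1", "18-24", "male", "white", 1, 20.0),
            ("A", "S1", "18-24", "male", "white", 0, 35.0),
            ("A", "S1", "25-29", "female", "non-white", 0, 12.0),
            ("B", "S1", "18-24", "male", "white", 1, 50.0),
            ("B", "S1", "30-35", "female", "white", 0, 8.0),
        ]
    )


@pytest.fixture
def random_records():
    """A hundred random but valid interviews over 6 counties in 2 states."""
    rng = np.random.default_rng(42)
    from bbz.survey import AGE_GROUPS, RACES, SEXES

    rows = []
    for _ in range(100):
        ci = rng.integers(6)
        rows.append(
            (
                f"C{ci}",
                f"S{ci // 3}",
                AGE_GROUPS[rng.integers(3)],
                SEXES[rng.integers(2)],
                RACES[rng.integers(2)],
                int(rng.random() < 0.2),
                float(1.0 + np.exp(rng.normal(2, 0.6))),
            )
        )
    return make_records(rows)


def single_cell_tables(y, n, hist=()):
    """CellTable (and historical tables) holding one county x cluster cell."""
    def tbl(yy, nn):
        return pd.DataFrame(
            {
                "county": ["A"],
                "state": ["S"],
                "cluster": [1],
                "n": [nn],
                "y": [int(round(yy))],
                "y_eff": [float(yy)],
                "no_data": [False],
            }
        )

    return tbl(y, n), [tbl(Y0, n0) for Y0, n0 in hist]
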