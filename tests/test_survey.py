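import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bbz import survey
from bbz.survey import (
    AGE_GROUPS,
    RACES,
    SEXES,
    ConsistencyError,
    SchemaError,
    aggregate_cells,
    cluster_of,
    effective_counts,
    read_population,
    read_respondents,
    validate_respondents,
)

from .conftest import make_records


class TestClusterIndex:
    def test_cross_classification_is_a_bijection_onto_1_12(self):
        idx = {
            cluster_of(a, s, r)
            for a, s, r in itertools.product(AGE_GROUPS, SEXES, RACES)
        }
        assert idx == set(range(1, 13))

    def test_deterministic_and_injective(self):
        assert cluster_of("18-24", "male", "white") == cluster_of("18-24", "male", "white")
        assert cluster_of("18-24", "male", "white") != cluster_of("18-24", "male", "non-white")

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            cluster_of("80+", "male", "white")


class TestReadRespondents:
    def test_clean_file_round_trip(self, small_records, tmp_path):
        path = tmp_path / "r.csv"
        small_records.to_csv(path, index=False)
        report = read_respondents(path)
        assert len(report.records) == 5
        assert report.n_rejected == 0

    def test_low_weight_rejected_with_reason(self, small_records):
        df = small_records.copy()
        df.loc[2, "weight"] = 0.5
        report = validate_respondents(df)
        assert len(report.records) == 4
        assert report.n_rejected == 1
        assert "weight" in report.rejects["reason"].iloc[0]

    def test_county_under_two_states_is_fatal(self, small_records):
        df = small_records.copy()
        df.loc[1, "state"] = "S2"
        with pytest.raises(ConsistencyError):
            validate_respondents(df)

    def test_missing_column_is_schema_error(self, small_records):
        with pytest.raises(SchemaError):
            validate_respondents(small_records.drop(columns=["weight"]))

    def test_schema_mapping_renames_columns(self, small_records, tmp_path):
        renamed = small_records.rename(columns={"county": "cnty", "weight": "wt"})
        path = tmp_path / "r.csv"
        renamed.to_csv(path, index=False)
        report = read_respondents(path, schema={"county": "cnty", "weight": "wt"})
        assert len(report.records) == 5


class TestAggregation:
    def test_cell_sums_and_padding(self, small_records):
        cells = aggregate_cells(small_records)
        j = cluster_of("18-24", "male", "white")
        cell = cells.set_index(["county", "cluster"])
        assert cell.loc[("A", j), "n"] == 2
        assert cell.loc[("A", j), "y"] == 1
        # every county gets all 12 clusters, empty ones flagged
        assert len(cells) == 2 * 12
        assert cell.loc[("A", 7), "n"] == 0
        assert bool(cell.loc[("A", 7), "no_data"])

    def test_matches_brute_force_group_by(self, random_records):
        cells = aggregate_cells(random_records).set_index(["county", "cluster"])
        for (county, age, sex, race), grp in random_records.groupby(
            ["county", "age", "sex", "race"]
        ):
            j = cluster_of(age, sex, race)
            assert cells.loc[(county, j), "n"] == len(grp)
            assert cells.loc[(county, j), "y"] == grp["outcome"].sum()

    @given(st.randoms(use_true_random=False))
    def test_order_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2**31))
        rows = [
            (f"C{rng.integers(3)}", "S", AGE_GROUPS[rng.integers(3)],
             SEXES[rng.integers(2)], RACES[rng.integers(2)],
             int(rng.random() < 0.3), float(2 + 10 * rng.random()))
            for _ in range(30)
        ]
        df = make_records(rows)
        shuffled = df.sample(frac=1, random_state=1).reset_index(drop=True)
        a = aggregate_cells(df).set_index(["county", "cluster"])
        b = aggregate_cells(shuffled).set_index(["county", "cluster"])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            cells = aggregate_cells(make_records([]))
        assert len(cells) == 0


class TestEffectiveCounts:
    def test_t_zero_recovers_raw_counts_exactly(self, random_records):
        cells = effective_counts(random_records, T=0.0)
        assert np.array_equal(cells["y_eff"].to_numpy(), cells["y"].to_numpy(dtype=float))

    def test_constant_weights_recover_raw_counts_at_any_t(self):
        rows = [("A", "S", "18-24", "male", "white", y, 12.5) for y in (1, 0, 1, 1, 0)]
        for T in (0.3, 0.7, 1.0):
            cells = effective_counts(make_records(rows), T=T)
            got = cells.loc[cells["n"] > 0, ["y", "y_eff"]]
            assert np.array_equal(got["y_eff"].to_numpy(), got["y"].to_numpy(dtype=float))

    def test_hand_computed_cell(self):
        # outcomes {1, 0}, weights {e^4, e}: log-weights {4, 1}, so the
        # tilted proportion is 4/5 and y_eff = (4/5) * 2 = 1.6 at T = 1
        rows = [
            ("A", "S", "18-24", "male", "white", 1, float(np.exp(4))),
            ("A", "S", "18-24", "male", "white", 0, float(np.exp(1))),
        ]
        cells = effective_counts(make_records(rows), T=1.0)
        got = cells.loc[cells["n"] == 2, "y_eff"].iloc[0]
        assert got == pytest.approx(1.6, abs=1e-12)

    def test_literal_rescaling_uses_y(self):
        rows = [
            ("A", "S", "18-24", "male", "white", 1, float(np.exp(4))),
            ("A", "S", "18-24", "male", "white", 0, float(np.exp(1))),
        ]
        cells = effective_counts(make_records(rows), T=1.0, literal_eq34=True)
        got = cells.loc[cells["n"] == 2, "y_eff"].iloc[0]
        assert got == pytest.approx(0.8, abs=1e-12)

    def test_monotone_in_t_when_cases_carry_larger_weights(self):
        rows = [
            ("A", "S", "18-24", "male", "white", 1, float(np.exp(5))),
            ("A", "S", "18-24", "male", "white", 1, float(np.exp(4))),
            ("A", "S", "18-24", "male", "white", 0, float(np.exp(2))),
            ("A", "S", "18-24", "male", "white", 0, float(np.exp(1.5))),
        ]
        df = make_records(rows)
        grid = np.linspace(0, 1, 11)
        vals = [
            effective_counts(df, T=t).query("n > 0")["y_eff"].iloc[0] for t in grid
        ]
        assert np.all(np.diff(vals) > 0)

    def test_bounds_hold(self, random_records):
        for T in (0.0, 0.5, 1.0):
            cells = effective_counts(random_records, T=T)
            assert (cells["y_eff"] >= -1e-12).all()
            assert (cells["y_eff"] <= cells["n"] + 1e-12).all()

    def test_invalid_t_rejected(self, small_records):
        with pytest.raises(ValueError):
            effective_counts(small_records, T=1.5)


class TestReadPopulation:
    def test_clean_table(self, tmp_path):
        df = pd.DataFrame(
            {"county": ["A"] * 12, "cluster": range(1, 13), "population": 1000.0}
        )
        path = tmp_path / "pop.csv"
        df.to_csv(path, index=False)
        pop = read_population(path)
        assert len(pop) == 12

    def test_nonpositive_population_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"county": ["A", "A"], "cluster": [1, 2], "population": [0.0, 10.0]}
        )
        path = tmp_path / "pop.csv"
        df.to_csv(path, index=False)
        pop = read_population(path)
        assert len(pop) == 1
        assert len(pop.attrs["rejects"]) == 1

    def test_duplicate_cell_is_fatal(self, tmp_path):
        df = pd.DataFrame(
            {"county": ["A", "A"], "cluster": [1, 1], "population": [5.0, 10.0]}
        )
        path = tmp_path / "pop.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ConsistencyError):
            read_population(path)

    def test_demographic_columns_accepted(self, tmp_path):
        df = pd.DataFrame(
            {
                "county": ["A"],
                "age": ["18-24"],
                "sex": ["male"],
                "race": ["white"],
                "population": [500.0],
            }
        )
        path = tmp_path / "pop.csv"
        df.to_csv(path, index=False)
        pop = read_population(path)
        assert pop["cluster"].iloc[0] == survey.cluster_of("18-24", "male", "white")
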