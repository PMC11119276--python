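"""Respondent-level survey records and county x cluster aggregation.

A survey dataset is a table of interviews: county, state, three demographic
attributes (age group, sex, race), a binary outcome, and a positive design
weight.  Respondents are cross-classified into 12 demographic clusters
(3 age groups x 2 sexes x 2 races).  Models downstream never see individual
interviews: they see county x cluster cells with a sample size ``n``, a raw
case count ``y`` and, when sampling weights are used, an "effective" case
count ``y_eff`` built from log-transformed weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_GROUPS = ("18-24", "25-29", "30-35")
SEXES = ("male", "female")
RACES = ("white", "non-white")

N_CLUSTERS = 12

#: canonical respondent-table column names
RESPONDENT_COLUMNS = ("county", "state", "age", "sex", "race", "outcome", "weight")

CELL_COLUMNS = ("county", "state", "cluster", "n", "y", "y_eff", "no_data")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ConsistencyError(ValueError):
    """The dataset contradicts itself (e.g. one county under two states)."""


def cluster_of(age: str, sex: str, race: str) -> int:
    """Map (age group, sex, race) to the cluster index in 1..12.

    The mapping is fixed lexicographic order: age varies slowest, race
    fastest, so ("18-24", "male", "white") -> 1 and ("30-35", "female",
    "non-white") -> 12.  It is stable across runs by construction.
    """
    try:
        a = AGE_GROUPS.index(age)
        s = SEXES.index(sex)
        r = RACES.index(race)
    except ValueError as exc:
        raise ValueError(
            f"invalid demographic value in ({age!r}, {sex!r}, {race!r})"
        ) from exc
    return a * 4 + s * 2 + r + 1


def cluster_labels() -> pd.DataFrame:
    """The full 12-row (cluster, age, sex, race) lookup table."""
    rows = [
        {"cluster": cluster_of(a, s, r), "age": a, "sex": s, "race": r}
        for a in AGE_GROUPS
        for s in SEXES
        for r in RACES
    ]
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)


@dataclass
class ReadReport:
    """Validated respondent records plus the rows that were rejected."""

    records: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


def validate_respondents(df: pd.DataFrame) -> ReadReport:
    """Validate a respondent table row by row.

    Rows violating record-level invariants (outcome not in {0, 1}, weight
    not a number > 1, unknown demographic level) are rejected with a reason
    and reported; a county appearing under two states is a fatal
    :class:`ConsistencyError`.
    """
    missing = [c for c in RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    weight = pd.to_numeric(df["weight"], errors="coerce")
    bad_w = ~(weight > 1.0)
    reasons[bad_w & (reasons == "")] = "weight <= 1 or non-numeric"

    outcome = pd.to_numeric(df["outcome"], errors="coerce")
    bad_y = ~outcome.isin([0, 1])
    reasons[bad_y & (reasons == "")] = "outcome not in {0, 1}"

    bad_demo = (
        ~df["age"].isin(AGE_GROUPS)
        | ~df["sex"].isin(SEXES)
        | ~df["race"].isin(RACES)
    )
    reasons[bad_demo & (reasons == "")] = "invalid demographic level"

    bad = reasons != ""
    rejects = df[bad].copy()
    rejects["reason"] = reasons[bad]

    good = df[~bad].copy()
    good["weight"] = weight[~bad].astype(float)
    good["outcome"] = outcome[~bad].astype(int)
    good["county"] = good["county"].astype(str)
    good["state"] = good["state"].astype(str)

    states_per_county = good.groupby("county")["state"].nunique()
    multi = states_per_county[states_per_county > 1]
    if len(multi):
        raise ConsistencyError(
            f"counties mapped to more than one state: {list(multi.index)}"
        )
    return ReadReport(records=good.reset_index(drop=True), rejects=rejects)


def read_respondents(path, schema: dict | None = None) -> ReadReport:
    """Read a respondent CSV, renaming columns via ``schema`` if given.

    ``schema`` maps canonical names (see :data:`RESPONDENT_COLUMNS`) to the
    column names actually present in the file.
    """
    df = pd.read_csv(path, dtype={0: str})
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_respondents(df)


def _with_cluster(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["cluster"] = [
        cluster_of(a, s, r)
        for a, s, r in zip(out["age"], out["sex"], out["race"])
    ]
    return out


def aggregate_cells(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate respondents into county x cluster cells.

    Every county present in the input gets all 12 cluster rows; clusters
    with no interviews get n = y = 0 and ``no_data=True``.  ``y_eff`` is
    initialized to the raw count (the unweighted limit); use
    :func:`effective_counts` to fill it from sampling weights.
    """
    if len(records) == 0:
        import warnings

        warnings.warn("aggregating an empty respondent table", stacklevel=2)
        return pd.DataFrame(columns=list(CELL_COLUMNS))

    rec = _with_cluster(records)
    g = rec.groupby(["county", "cluster"], sort=True)
    agg = g.agg(n=("outcome", "size"), y=("outcome", "sum")).reset_index()

    county_state = rec.drop_duplicates("county").set_index("county")["state"]
    counties = sorted(rec["county"].unique())
    full = pd.MultiIndex.from_product(
        [counties, range(1, N_CLUSTERS + 1)], names=["county", "cluster"]
    )
    cells = (
        agg.set_index(["county", "cluster"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    cells["state"] = cells["county"].map(county_state)
    cells["no_data"] = cells["n"] == 0
    cells["y_eff"] = cells["y"].astype(float)
    return cells[list(CELL_COLUMNS)]


def effective_counts(
    records: pd.DataFrame, T: float, literal_eq34: bool = False
) -> pd.DataFrame:
    """Aggregate cells and fill the log-weight effective case counts.

    For cell (i, j) with respondent outcomes y_k and weights w_k,

        y_eff = n * sum_k (log w_k)^T y_k / sum_k (log w_k)^T

    i.e. the log-weight-tilted case proportion rescaled by the cell sample
    size.  T in [0, 1] tunes the strength of the weight adjustment: T = 0
    recovers the raw counts exactly, T = 1 is the fully weighted
    adjustment.  ``literal_eq34=True`` rescales by y instead of n (for
    auditing; it does not reproduce raw counts at T = 0).

    Weights must exceed 1 so log(w) > 0; validated records guarantee this.
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"T must lie in [0, 1], got {T}")
    cells = aggregate_cells(records)
    if len(cells) == 0:
        return cells
    if np.any(records["weight"].to_numpy() <= 1.0):
        raise AssertionError("internal invariant violated: weight <= 1 survived validation")

    rec = _with_cluster(records)
    lw = np.log(rec["weight"].to_numpy(dtype=float)) ** T
    rec = rec.assign(_lw=lw, _lwy=lw * rec["outcome"].to_numpy())
    g = rec.groupby(["county", "cluster"])
    sums = g.agg(
        lw_sum=("_lw", "sum"),
        lwy_sum=("_lwy", "sum"),
        w_min=("weight", "min"),
        w_max=("weight", "max"),
    )

    cells = cells.set_index(["county", "cluster"])
    prop = (sums["lwy_sum"] / sums["lw_sum"]).reindex(cells.index)
    scale = cells["y"] if literal_eq34 else cells["n"]
    y_eff = (prop * scale).fillna(0.0)

    # T = 0 and constant-weight cells reduce algebraically to the raw count;
    # short-circuit so the identity is exact in floating point too.
    if not literal_eq34:
        exact = pd.Series(False, index=cells.index)
        if T == 0.0:
            exact[:] = True
        else:
            const = (sums["w_min"] == sums["w_max"]).reindex(cells.index, fill_value=False)
            exact |= const
        y_eff[exact] = cells.loc[exact, "y"].astype(float)

    cells["y_eff"] = y_eff
    return cells.reset_index()[list(CELL_COLUMNS)]


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Check CellTable invariants; returns the table unchanged if valid."""
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise SchemaError(f"cell table missing column {col!r}")
    n = cells["n"].to_numpy()
    y = cells["y"].to_numpy()
    ye = cells["y_eff"].to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("cell invariant violated: need 0 <= y <= n")
    if np.any(ye < -1e-9) or np.any(ye > n + 1e-9):
        raise ValueError("cell invariant violated: need 0 <= y_eff <= n")
    zero = n == 0
    if np.any(y[zero] != 0) or np.any(ye[zero] != 0):
        raise ValueError("cells with n = 0 must have y = y_eff = 0")
    if cells.duplicated(["county", "cluster"]).any():
        raise ConsistencyError("duplicate (county, cluster) cells")
    return cells


def read_population(path) -> pd.DataFrame:
    """Read a county x cluster population-projection table.

    Accepts either (county, cluster, population) columns or the three
    demographic columns in place of ``cluster``.  Rows with nonpositive
    population are rejected (reported on the returned frame's
    ``attrs['rejects']``); duplicate (county, cluster) keys are fatal.
    """
    df = pd.read_csv(path, dtype={"county": str})
    if "cluster" not in df.columns:
        if not {"age", "sex", "race"}.issubset(df.columns):
            raise SchemaError(
                "population file needs a 'cluster' column or age/sex/race columns"
            )
        df["cluster"] = [
            cluster_of(a, s, r) for a, s, r in zip(df["age"], df["sex"], df["race"])
        ]
    if "population" not in df.columns or "county" not in df.columns:
        raise SchemaError("population file needs 'county' and 'population' columns")

    pop = pd.to_numeric(df["population"], errors="coerce")
    bad = ~(pop > 0)
    rejects = df[bad].copy()
    rejects["reason"] = "nonpositive or non-numeric population"
    out = df[~bad].copy()
    out["population"] = pop[~bad].astype(float)
    out["county"] = out["county"].astype(str)
    if out.duplicated(["county", "cluster"]).any():
        dups = out[out.duplicated(["county", "cluster"], keep=False)]
        raise ConsistencyError(
            f"duplicate (county, cluster) population rows:\n{dups[['county', 'cluster']]}"
        )
    out = out[["county", "cluster", "population"]].reset_index(drop=True)
    out.attrs["rejects"] = rejects
    return out
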