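"""Synthetic survey generator with the structure the models assume.

The generator emulates a BRFSS-like state-level telephone survey of a
rare condition: counties nested in states, respondents cross-classified
into the 12 demographic clusters, positive expansion weights, a fraction
of counties that are *structural* zeros (the condition is absent there,
so every interview is a non-case), and optional historical survey years
drawn from the same truth with a log-odds drift.

Truth generation follows the hierarchical logit model: cell
probabilities p_ij = expit(beta_j + mu_ij + v_sj) with county and state
random effects; structural-zero counties get p_ij = 0.  Informative
sampling is created by tilting case inclusion: with coupling kappa > 0,
sampled outcomes are drawn at logit(p) + kappa (cases oversampled) and
cases receive systematically smaller weights, so the unweighted
estimator is biased upward by a known direction — the bias the
log-weight effective counts exist to reduce.

Also here: the pseudo-county harness, which resamples county blocks and
thins cases to hit an exact target fraction of zero-count counties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import survey

#: default cluster fixed effects: overall prevalence near 0.8%, mildly
#: higher in the older age groups and for the non-white race group
DEFAULT_BETA = tuple(
    -4.9 + 0.15 * a + 0.1 * s + 0.2 * r
    for a in range(3)
    for s in range(2)
    for r in range(2)
)


@dataclass
class SimConfig:
    """Generator settings; defaults give a rare outcome (~0.8% pooled).

    ``omega_dist`` is the (mean, concentration) of the Beta distribution
    from which each county's structural-zero probability omega_i is
    drawn.  ``weight_dist`` parameterizes log(w - 1) ~ Normal(meanlog,
    sdlog), keeping every weight above 1.  ``informative_weighting``
    (kappa) couples sampling and outcome: sampled outcomes use
    logit(p) + kappa and cases get weights with meanlog reduced by
    kappa.  ``drift`` shifts historical-year log-odds.
    """

    n_states: int = 5
    counties_per_state: int = 20
    beta_true: tuple = DEFAULT_BETA
    sigma_mu_true: float = 0.3
    sigma_v_true: float = 0.2
    omega_dist: tuple[float, float] = (0.3, 6.0)
    respondents_per_county: int | tuple[int, int] = 50
    weight_dist: tuple[float, float] = (2.0, 0.5)
    informative_weighting: float = 0.5
    n_historical_years: int = 2
    drift: float = 0.0
    current_year: int = 2019
    seed: int = 0

    def __post_init__(self):
        if len(self.beta_true) != survey.N_CLUSTERS:
            raise ValueError("beta_true must have length 12")
        m, c = self.omega_dist
        if not (0.0 <= m <= 1.0) or c <= 0:
            raise ValueError("omega_dist must be (mean in [0,1], concentration > 0)")
        p = expit(np.asarray(self.beta_true))
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("beta_true implies probabilities outside (0, 1)")


@dataclass
class SyntheticTruth:
    """Everything needed to score an estimator without re-simulation."""

    counties: list
    states: list
    state_of_county: np.ndarray
    p_cell: np.ndarray            # (C, 12); zero rows for structural counties
    p_latent: np.ndarray          # (C, 12) logit-model probabilities pre-zeroing
    structural: pd.Series         # bool per county
    omega: pd.Series              # county structural-zero probability
    population: pd.DataFrame      # county x cluster projections
    p_county: pd.Series = field(init=False)
    config: SimConfig | None = None

    def __post_init__(self):
        N = (
            self.population.pivot(index="county", columns="cluster", values="population")
            .reindex(index=self.counties, columns=range(1, survey.N_CLUSTERS + 1))
            .to_numpy()
        )
        agg = (self.p_cell * N).sum(axis=1) / N.sum(axis=1)
        self.p_county = pd.Series(agg, index=self.counties)


def _county_ids(config: SimConfig):
    counties, states, soc = [], [], []
    for s in range(config.n_states):
        states.append(f"S{s + 1:02d}")
        for c in range(config.counties_per_state):
            counties.append(f"S{s + 1:02d}-C{c + 1:03d}")
            soc.append(s)
    return counties, states, np.array(soc)


def _respondents_for(config: SimConfig, rng, n_counties: int) -> np.ndarray:
    r = config.respondents_per_county
    if isinstance(r, tuple):
        lo, hi = r
        return rng.integers(lo, hi + 1, size=n_counties)
    return np.full(n_counties, int(r))


def _draw_records(
    truth: SyntheticTruth, config: SimConfig, rng, year: int, logodds_shift: float
) -> pd.DataFrame:
    """Draw one survey year from the truth with a log-odds shift."""
    kappa = config.informative_weighting
    meanlog, sdlog = config.weight_dist
    labels = survey.cluster_labels().set_index("cluster")
    N = (
        truth.population.pivot(index="county", columns="cluster", values="population")
        .reindex(index=truth.counties, columns=range(1, survey.N_CLUSTERS + 1))
        .to_numpy()
    )
    n_resp = _respondents_for(config, rng, len(truth.counties))

    frames = []
    for ci, county in enumerate(truth.counties):
        n = int(n_resp[ci])
        shares = N[ci] / N[ci].sum()
        clusters = rng.choice(survey.N_CLUSTERS, size=n, p=shares) + 1
        p = truth.p_cell[ci, clusters - 1]
        if logodds_shift != 0.0:
            with np.errstate(divide="ignore"):
                p = np.where(p > 0, expit(logit(p) + logodds_shift), 0.0)
        # inclusion tilt: sampled case odds are population odds * e^kappa
        with np.errstate(divide="ignore"):
            p_samp = np.where(p > 0, expit(logit(p) + kappa), 0.0)
        y = rng.binomial(1, p_samp)
        w = 1.0 + np.exp(rng.normal(meanlog - kappa * y, sdlog))
        demo = labels.loc[clusters]
        frames.append(
            pd.DataFrame(
                {
                    "county": county,
                    "state": truth.states[truth.state_of_county[ci]],
                    "age": demo["age"].to_numpy(),
                    "sex": demo["sex"].to_numpy(),
                    "race": demo["race"].to_numpy(),
                    "outcome": y,
                    "weight": w,
                    "year": year,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_survey(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the current survey year and its generating truth.

    Deterministic given ``config.seed``; the returned records satisfy
    every respondent-record invariant by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    counties, states, soc = _county_ids(config)
    C, J = len(counties), survey.N_CLUSTERS

    beta = np.asarray(config.beta_true, dtype=float)
    mu = config.sigma_mu_true * rng.standard_normal((C, J))
    v = config.sigma_v_true * rng.standard_normal((len(states), J))
    p_latent = expit(beta[None, :] + mu + v[soc])

    m, conc = config.omega_dist
    if m <= 0:
        omega = np.zeros(C)
    elif m >= 1:
        omega = np.ones(C)
    else:
        omega = rng.beta(m * conc, (1 - m) * conc, size=C)
    structural = rng.uniform(size=C) < omega
    p_cell = np.where(structural[:, None], 0.0, p_latent)

    pop = pd.DataFrame(
        {
            "county": np.repeat(counties, J),
            "cluster": np.tile(np.arange(1, J + 1), C),
            "population": np.exp(rng.normal(7.0, 0.4, size=C * J)),
        }
    )

    truth = SyntheticTruth(
        counties=counties,
        states=states,
        state_of_county=soc,
        p_cell=p_cell,
        p_latent=p_latent,
        structural=pd.Series(structural, index=counties),
        omega=pd.Series(omega, index=counties),
        population=pop,
        config=config,
    )
    records = _draw_records(truth, config, rng, config.current_year, 0.0)
    return records, truth


def generate_historical(truth: SyntheticTruth, config: SimConfig) -> list[pd.DataFrame]:
    """Draw ``n_historical_years`` survey years from the same truth.

    Each year's log-odds are shifted by ``drift`` (zero drift makes the
    years exchangeable with the current one); structural-zero counties
    remain all-zero in every year.
    """
    out = []
    for h in range(config.n_historical_years):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1 + h,))
        )
        out.append(
            _draw_records(
                truth, config, rng, config.current_year - 1 - h, config.drift
            )
        )
    return out


def make_pseudo_counties(
    records: pd.DataFrame,
    target_zero_fraction: float,
    n_counties: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resample county blocks into pseudo-counties with an exact zero level.

    Draws ``n_counties`` county blocks with replacement, then adjusts so
    that exactly ``round(target_zero_fraction * n_counties)`` of them
    have zero cases: surplus zero blocks are replaced by draws from the
    non-zero pool, and shortfalls are created by *thinning* randomly
    chosen non-zero blocks (removing their case interviews).  Each
    pseudo-county keeps its source county's state.

    Returns the resampled records and a provenance table mapping each
    pseudo-county to its source county (with a ``thinned`` flag).
    """
    if not 0.0 <= target_zero_fraction <= 1.0:
        raise ValueError("target_zero_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cases = records.groupby("county")["outcome"].sum()
    all_counties = np.array(sorted(cases.index))
    nonzero_pool = np.array(sorted(cases.index[cases > 0]))
    k = int(round(target_zero_fraction * n_counties))

    if k < n_counties and len(nonzero_pool) == 0:
        raise ValueError(
            "infeasible target: source has no counties with cases, cannot "
            f"produce {n_counties - k} non-zero pseudo-counties"
        )
    if len(all_counties) == 0:
        raise ValueError("empty source dataset")

    chosen = rng.choice(all_counties, size=n_counties, replace=True)
    is_zero = np.array([cases[c] == 0 for c in chosen])
    thin = np.zeros(n_counties, dtype=bool)

    surplus = int(is_zero.sum()) - k
    if surplus > 0:
        idx = rng.choice(np.where(is_zero)[0], size=surplus, replace=False)
        chosen[idx] = rng.choice(nonzero_pool, size=surplus, replace=True)
        is_zero[idx] = False
    elif surplus < 0:
        idx = rng.choice(np.where(~is_zero)[0], size=-surplus, replace=False)
        thin[idx] = True
        is_zero[idx] = True

    frames = []
    prov = []
    grouped = {c: g for c, g in records.groupby("county")}
    for t, (src, do_thin) in enumerate(zip(chosen, thin)):
        block = grouped[src].copy()
        if do_thin:
            block = block[block["outcome"] == 0]
        pid = f"P{t + 1:04d}"
        block["county"] = pid
        frames.append(block)
        prov.append({"pseudo": pid, "source": src, "thinned": bool(do_thin)})
    out = pd.concat(frames, ignore_index=True)
    return out, pd.DataFrame(prov)


def pseudo_population(
    provenance: pd.DataFrame, population: pd.DataFrame
) -> pd.DataFrame:
    """Population table for pseudo-counties, copied from their sources."""
    frames = []
    by_county = {c: g for c, g in population.groupby("county")}
    for _, row in provenance.iterrows():
        block = by_county[row["source"]].copy()
        block["county"] = row["pseudo"]
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def write_dataset(path, records, truth: SyntheticTruth, historical=()) -> None:
    """Write respondent CSV(s), population CSV and a truth JSON to a
    directory; all files round-trip through the survey readers."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records.to_csv(path / "respondents.csv", index=False)
    truth.population.to_csv(path / "population.csv", index=False)
    for h, df in enumerate(historical):
        df.to_csv(path / f"historical_{h + 1}.csv", index=False)
    payload = {
        "p_county": {c: float(v) for c, v in truth.p_county.items()},
        "omega": {c: float(v) for c, v in truth.omega.items()},
        "structural": {c: bool(v) for c, v in truth.structural.items()},
        "p_cell": truth.p_cell.tolist(),
        "counties": truth.counties,
        "states": truth.states,
    }
    (path / "truth.json").write_text(json.dumps(payload))
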