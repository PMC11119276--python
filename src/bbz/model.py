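"""The four-variant hierarchical prevalence model.

County x cluster case counts are modelled binomially on the logit scale,

    y_ij ~ Binomial(n_ij, p_ij),
    logit(p_ij) = beta_j + Z gamma + mu_ij + v_{s(i)j},

with county random effects mu_ij ~ N(0, sigma_mu^2) and state random
effects v_sj ~ N(0, sigma_v^2).  Three optional features are layered on
this base:

* **weights** — replace y_ij by the log-weight effective count y_eff_ij;
* **power prior** — add alpha0-tempered likelihood terms for one or more
  historical years of the same survey;
* **zero inflation** — mix a county-level point mass omega_i at zero into
  the cell likelihood, separating structural from sampling zeros.

The four named variants are the corners of this feature lattice:
BHBI (none), BZBI (zero inflation), BPLW (weights + power prior) and
BBZ (all three).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from . import likelihoods, survey

#: variant name -> (use_weights, use_power_prior, use_zero_inflation)
VARIANTS = {
    "BHBI": (False, False, False),
    "BZBI": (False, False, True),
    "BPLW": (True, True, False),
    "BBZ": (True, True, True),
}


@dataclass
class ModelSpec:
    """Which features are active, plus priors and hyperparameters.

    Parameters
    ----------
    use_weights
        Fit the effective counts ``y_eff`` (computed with tuning exponent
        ``T``) instead of the raw counts.
    T
        Log-weight tuning exponent in [0, 1]; 0 is unweighted, 1 fully
        weighted.  Recorded here for provenance; the effective counts are
        computed at aggregation time.
    use_power_prior, alpha0
        Borrow from historical years by tempering their likelihood with
        alpha0 in (0, 1].
    use_zero_inflation
        County-level structural-zero mixture weight omega_i.
    prior_fixed_sd
        SD of the Normal(0, .) prior on the fixed effects beta (and any
        covariate coefficients gamma); default 1000 (variance 10^6), a
        flat prior on the logit scale.
    prior_re_scale
        Half-Normal scale for the random-effect SDs sigma_mu, sigma_v.
    prior_omega_logit_sd
        SD of the Normal prior on logit(omega_i).  The default 1.8 makes
        the implied prior on omega_i close to uniform on (0, 1) — the
        non-informative choice on the probability scale.  (A very wide
        logit-normal would instead pile mass on {0, 1}.)
    include_county_re, include_state_re
        Switch the random-effect levels off for reduced models (used by
        the single-cell conjugate reduction).
    beta_prior_beta
        Optional (a, b): replace the Normal prior on each beta_j by the
        prior induced by p_j = expit(beta_j) ~ Beta(a, b).  Only
        meaningful with random effects off; exists so the MCMC can be
        checked against the closed-form conjugate posterior.
    """

    use_weights: bool = False
    T: float = 1.0
    use_power_prior: bool = False
    alpha0: float = 0.5
    use_zero_inflation: bool = False
    prior_fixed_sd: float = 1000.0
    prior_re_scale: float = 1.0
    prior_omega_logit_sd: float = 1.8
    include_county_re: bool = True
    include_state_re: bool = True
    beta_prior_beta: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.T <= 1.0:
            raise ValueError(f"T must lie in [0, 1], got {self.T}")
        if self.use_power_prior and not 0.0 < self.alpha0 <= 1.0:
            raise ValueError(f"alpha0 must lie in (0, 1], got {self.alpha0}")
        for name in ("prior_fixed_sd", "prior_re_scale", "prior_omega_logit_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_variant(cls, name: str, **overrides) -> "ModelSpec":
        """Build the spec for one of BHBI, BZBI, BPLW, BBZ."""
        try:
            w, pp, zi = VARIANTS[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
            ) from None
        return cls(
            use_weights=w, use_power_prior=pp, use_zero_inflation=zi, **overrides
        )

    @property
    def variant_name(self) -> str:
        key = (self.use_weights, self.use_power_prior, self.use_zero_inflation)
        for name, flags in VARIANTS.items():
            if flags == key:
                return name
        return "custom"

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


@dataclass
class ParameterState:
    """One point in parameter space (non-centered parameterization).

    ``u_mu`` and ``u_v`` are the standardized random effects; the actual
    effects are mu = sigma_mu * u_mu and v = sigma_v * u_v.  ``logit_omega``
    is None when zero inflation is off; ``gamma`` is empty without
    covariates.
    """

    beta: np.ndarray                      # (J,)
    u_mu: np.ndarray                      # (C, J)
    u_v: np.ndarray                       # (S, J)
    log_sigma_mu: float
    log_sigma_v: float
    logit_omega: np.ndarray | None = None  # (C,)
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def sigma_mu(self) -> float:
        return float(np.exp(self.log_sigma_mu))

    @property
    def sigma_v(self) -> float:
        return float(np.exp(self.log_sigma_v))

    @property
    def omega(self) -> np.ndarray | None:
        if self.logit_omega is None:
            return None
        return expit(self.logit_omega)

    def copy(self) -> "ParameterState":
        return ParameterState(
            beta=self.beta.copy(),
            u_mu=self.u_mu.copy(),
            u_v=self.u_v.copy(),
            log_sigma_mu=self.log_sigma_mu,
            log_sigma_v=self.log_sigma_v,
            logit_omega=None if self.logit_omega is None else self.logit_omega.copy(),
            gamma=self.gamma.copy(),
        )


class PrevalenceModel:
    """A small-area prevalence model bound to one survey's cell table.

    Parameters
    ----------
    cells
        CellTable (see :mod:`bbz.survey`) for the current year.
    spec
        :class:`ModelSpec`; defaults to the full BBZ feature set when
        historical tables are supplied, BHBI otherwise.
    historical
        Zero or more CellTables of historical years, aligned on county
        and cluster (counties missing from a year contribute nothing).
    covariates
        Optional (C, J, q) array of auxiliary cell-level covariates with
        coefficients gamma.

    ``fit()`` draws from the posterior by MCMC and returns a
    :class:`~bbz.results.PrevalenceResults`.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        spec: ModelSpec | None = None,
        historical: Sequence[pd.DataFrame] = (),
        covariates: np.ndarray | None = None,
    ):
        survey.validate_cells(cells)
        if spec is None:
            spec = ModelSpec.from_variant("BBZ" if len(historical) else "BHBI")
        self.spec = spec
        self.cells = cells.reset_index(drop=True)

        self.counties = sorted(cells["county"].unique())
        self.clusters = sorted(cells["cluster"].unique())
        county_state = cells.drop_duplicates("county").set_index("county")["state"]
        self.states = sorted(county_state.unique())
        self.state_of_county = np.array(
            [self.states.index(county_state[c]) for c in self.counties]
        )
        self.C, self.J, self.S = len(self.counties), len(self.clusters), len(self.states)

        self.n = self._pivot(cells, "n")
        self.y_raw = self._pivot(cells, "y")
        self.y_eff = self._pivot(cells, "y_eff")
        self.y = self.y_eff if spec.use_weights else self.y_raw
        self.mask = self.n > 0

        self.historical = []
        if historical and not spec.use_power_prior:
            raise ValueError(
                "historical tables supplied but use_power_prior is off"
            )
        if spec.use_power_prior and not historical:
            raise ValueError("use_power_prior requires at least one historical table")
        for h in historical:
            survey.validate_cells(h)
            extra = set(h["county"]) - set(self.counties)
            if extra:
                raise ValueError(
                    f"historical table has counties absent from current data: {sorted(extra)[:5]}"
                )
            n0 = self._pivot(h, "n")
            y0 = self._pivot(h, "y_eff" if spec.use_weights else "y")
            self.historical.append((n0, y0))

        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)
            if covariates.shape[:2] != (self.C, self.J):
                raise ValueError("covariates must have shape (C, J, q)")
        self.covariates = covariates
        self.n_covariates = 0 if covariates is None else covariates.shape[2]

        # cached likelihood ingredients (lgamma terms are parameter-free);
        # current + historical years stacked on a leading axis, with the
        # alpha0 tempering as per-year weights
        self._cur_tbl = self._prep_table(self.y, self.n)
        self._hist_tbl = [self._prep_table(y0, n0) for n0, y0 in self.historical]
        tbls = [self._cur_tbl] + self._hist_tbl
        self._stack = {
            key: np.stack([t[key] for t in tbls])
            for key in ("y", "n", "mask", "coef", "zero", "pos", "y_is_zero", "y_is_n")
        }
        self._year_w = np.concatenate(
            [[1.0], np.full(len(self._hist_tbl), spec.alpha0)]
        )[:, None, None]

    @staticmethod
    def _prep_table(y, n):
        from scipy.special import gammaln

        mask = n > 0
        coef = np.where(
            mask, gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0), 0.0
        )
        return {
            "y": y,
            "n": n,
            "mask": mask,
            "coef": coef,
            "zero": mask & (y == 0),
            "pos": mask & (y > 0),
            "y_is_zero": y == 0,
            "y_is_n": y == n,
        }

    def _table_ll(self, tbl, log_p, log_q, omega):
        """Per-cell log-likelihood of one year's table from cached terms.

        log_p = log expit(eta), log_q = log expit(-eta) = log(1 - p).
        Works on a single table (C, J) or the stacked years (K, C, J).
        """
        # guard the 0 * (-inf) corners: y = 0 contributes no log p term and
        # y = n no log(1-p) term, even when the probability saturates
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = np.where(tbl["y_is_zero"], 0.0, tbl["y"] * log_p)
            t_q = np.where(tbl["y_is_n"], 0.0, (tbl["n"] - tbl["y"]) * log_q)
            binom = tbl["coef"] + t_p + t_q
            if not self.spec.use_zero_inflation:
                return np.where(tbl["mask"], binom, 0.0)
            om = omega[:, None] if omega.ndim == 1 else omega
            log_om = np.log(om)
            log_1m = np.log1p(-om)
            zero_branch = np.logaddexp(
                log_om, log_1m + np.where(tbl["mask"], tbl["n"] * log_q, 0.0)
            )
            return np.where(
                tbl["zero"], zero_branch, np.where(tbl["pos"], log_1m + binom, 0.0)
            )

    def _pivot(self, cells: pd.DataFrame, col: str) -> np.ndarray:
        wide = cells.pivot(index="county", columns="cluster", values=col)
        wide = wide.reindex(index=self.counties, columns=self.clusters)
        return np.nan_to_num(wide.to_numpy(dtype=float), nan=0.0)

    # ---------------------------------------------------------------- core

    def linear_predictor(self, state: ParameterState, i=None, j=None):
        """eta_ij = beta_j + Z gamma + mu_ij + v_{s(i)j}; full (C, J) matrix,
        or one entry when county/cluster indices are given."""
        eta = np.broadcast_to(state.beta, (self.C, self.J)).copy()
        if self.covariates is not None and state.gamma.size:
            eta += self.covariates @ state.gamma
        if self.spec.include_county_re:
            eta += state.sigma_mu * state.u_mu
        if self.spec.include_state_re:
            eta += state.sigma_v * state.u_v[self.state_of_county]
        if i is None:
            return eta
        return float(eta[i, j])

    def cell_probs(self, state: ParameterState) -> np.ndarray:
        return expit(self.linear_predictor(state))

    def current_cell_loglik(self, eta: np.ndarray, omega: np.ndarray | None) -> np.ndarray:
        """Per-cell log-likelihood of the current year's data; 0 where n = 0."""
        return self._table_ll(self._cur_tbl, log_expit(eta), log_expit(-eta), omega)

    def historical_cell_loglik(self, eta: np.ndarray, omega: np.ndarray | None) -> np.ndarray:
        """Summed alpha0-tempered per-cell log-likelihood over historical years."""
        out = np.zeros((self.C, self.J))
        if not self.spec.use_power_prior:
            return out
        log_p, log_q = log_expit(eta), log_expit(-eta)
        for tbl in self._hist_tbl:
            out += self.spec.alpha0 * self._table_ll(tbl, log_p, log_q, omega)
        return out

    def cell_loglik(self, eta: np.ndarray, omega: np.ndarray | None) -> np.ndarray:
        """Current + tempered historical per-cell log-likelihood."""
        log_p, log_q = log_expit(eta), log_expit(-eta)
        if not self._hist_tbl:
            return self._table_ll(self._cur_tbl, log_p, log_q, omega)
        ll = self._table_ll(self._stack, log_p, log_q, omega)
        return np.einsum("kcj,k->cj", ll, self._year_w[:, 0, 0])

    def log_prior(self, state: ParameterState) -> float:
        spec = self.spec
        lp = 0.0
        if spec.beta_prior_beta is not None:
            a, b = spec.beta_prior_beta
            # induced prior: expit(beta_j) ~ Beta(a, b), Jacobian included
            lp += float(np.sum(a * log_expit(state.beta) + b * log_expit(-state.beta)))
        else:
            lp += float(-0.5 * np.sum((state.beta / spec.prior_fixed_sd) ** 2))
        if state.gamma.size:
            lp += float(-0.5 * np.sum((state.gamma / spec.prior_fixed_sd) ** 2))
        if spec.include_county_re:
            lp += float(-0.5 * np.sum(state.u_mu**2))
            # Half-Normal(scale) on sigma, plus the log-sigma Jacobian
            lp += -0.5 * (state.sigma_mu / spec.prior_re_scale) ** 2 + state.log_sigma_mu
        if spec.include_state_re:
            lp += float(-0.5 * np.sum(state.u_v**2))
            lp += -0.5 * (state.sigma_v / spec.prior_re_scale) ** 2 + state.log_sigma_v
        if spec.use_zero_inflation:
            if state.logit_omega is None:
                raise ValueError("zero inflation active but logit_omega missing")
            lp += float(
                -0.5 * np.sum((state.logit_omega / spec.prior_omega_logit_sd) ** 2)
            )
        return lp

    def log_posterior(self, state: ParameterState) -> float:
        """Joint log-posterior density (up to a constant)."""
        eta = self.linear_predictor(state)
        ll = self.cell_loglik(eta, state.omega)
        return float(np.sum(ll)) + self.log_prior(state)

    def deviance(self, p: np.ndarray, omega: np.ndarray | None) -> float:
        """-2 x current-data log-likelihood at cell probabilities p.

        Historical (tempered) terms are excluded: the deviance measures
        fit to the analyzed year only.
        """
        with np.errstate(divide="ignore"):
            log_p = np.log(p)
            log_q = np.log1p(-p)
        ll = self._table_ll(self._cur_tbl, log_p, log_q, omega)
        return float(-2.0 * np.sum(ll))

    # ----------------------------------------------------------- interface

    @classmethod
    def from_respondents(
        cls,
        records: pd.DataFrame,
        spec: ModelSpec | None = None,
        historical_records: Sequence[pd.DataFrame] = (),
        **kwargs,
    ) -> "PrevalenceModel":
        """Build the model straight from respondent tables.

        Effective counts for current and historical years are computed
        with the same tuning exponent ``spec.T``.
        """
        if spec is None:
            spec = ModelSpec.from_variant("BBZ" if len(historical_records) else "BHBI")
        T = spec.T if spec.use_weights else 0.0
        cells = survey.effective_counts(records, T)
        hist = [survey.effective_counts(h, T) for h in historical_records]
        return cls(cells, spec=spec, historical=hist, **kwargs)

    def fit(self, settings=None, progress: bool = False):
        """Run MCMC and return a :class:`~bbz.results.PrevalenceResults`."""
        from . import sampler  # local import: sampler imports this module
        from .results import PrevalenceResults

        if settings is None:
            settings = sampler.McmcSettings()
        draws = sampler.run_mcmc(self, settings, progress=progress)
        return PrevalenceResults(self, draws, settings)


def joint_log_posterior(
    state: ParameterState,
    current: pd.DataFrame,
    historical: Sequence[pd.DataFrame],
    spec: ModelSpec,
) -> float:
    """Functional form of :meth:`PrevalenceModel.log_posterior`."""
    return PrevalenceModel(current, spec=spec, historical=historical).log_posterior(state)
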