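"""Posterior sampling by adaptive Metropolis-within-Gibbs.

The posterior factorizes conveniently: given the fixed effects and the
random-effect scales, the standardized county effects u_mu[i, j] are
conditionally independent across cells, the state effects u_v[s, j]
across (state, cluster) pairs, and the zero-inflation weights omega_i
across counties.  Each block is therefore updated with *vectorized*
single-site random-walk Metropolis proposals — one matrix operation per
block per sweep — with per-block step sizes adapted during warmup toward
a 44% acceptance rate (the univariate optimum) and frozen afterwards.
The zero-inflation mixture is marginalized analytically in the
likelihood, so every sampled coordinate is continuous; omega_i is
sampled on the logit scale and the random effects are non-centered.

Also here: the closed-form Beta conjugate posterior for the single-cell
reduction of the model, used as an independent oracle for the sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import ModelSpec, ParameterState, PrevalenceModel

_ACCEPT_TARGET = 0.44


@dataclass
class McmcSettings:
    """Chain configuration and convergence thresholds."""

    chains: int = 4
    warmup_draws: int = 1000
    kept_draws: int = 1000
    seed: int = 0
    target_rhat: float = 1.01
    min_ess: int = 200

    def __post_init__(self):
        if self.kept_draws < 200:
            raise ValueError("kept_draws must be at least 200 for reported estimates")
        if self.chains < 1 or self.warmup_draws < 1:
            raise ValueError("chains and warmup_draws must be positive")


@dataclass
class PosteriorDraws:
    """MCMC output: per-draw parameters, derived cell probabilities p_ij
    (including no-data cells), per-draw deviance, and diagnostics.

    Arrays carry an explicit leading chain dimension; the ``*_flat``
    accessors pool chains.
    """

    beta: np.ndarray                       # (chains, D, J)
    p: np.ndarray                          # (chains, D, C, J)
    deviance: np.ndarray                   # (chains, D)
    log_sigma_mu: np.ndarray | None
    log_sigma_v: np.ndarray | None
    omega: np.ndarray | None               # (chains, D, C)
    counties: list
    states: list
    clusters: list
    seed: int
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        """Total kept draws pooled over chains."""
        return self.beta.shape[0] * self.beta.shape[1]

    def _flat(self, arr):
        return None if arr is None else arr.reshape((-1,) + arr.shape[2:])

    @property
    def beta_flat(self):
        return self._flat(self.beta)

    @property
    def p_flat(self):
        return self._flat(self.p)

    @property
    def omega_flat(self):
        return self._flat(self.omega)

    @property
    def deviance_flat(self):
        return self._flat(self.deviance)

    def convergence_failures(self, target_rhat=1.01, min_ess=200) -> pd.DataFrame:
        d = self.diagnostics
        if d.empty:
            return d
        return d[(d["rhat"] > target_rhat) | (d["ess"] < min_ess)]

    # -------------------------------------------------------- persistence

    def save(self, path) -> None:
        """Write one CSV per parameter block plus a JSON summary."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ch = np.repeat(np.arange(self.n_chains), self.beta.shape[1])

        def frame(flat, cols):
            df = pd.DataFrame(flat, columns=cols)
            df.insert(0, "chain", ch)
            return df

        frame(self.beta_flat, [f"beta_{j}" for j in self.clusters]).to_csv(
            path / "beta.csv", index=False
        )
        scal = {"deviance": self.deviance_flat}
        if self.log_sigma_mu is not None:
            scal["log_sigma_mu"] = self._flat(self.log_sigma_mu)
        if self.log_sigma_v is not None:
            scal["log_sigma_v"] = self._flat(self.log_sigma_v)
        frame(np.column_stack(list(scal.values())), list(scal)).to_csv(
            path / "scalars.csv", index=False
        )
        if self.omega is not None:
            frame(self.omega_flat, self.counties).to_csv(path / "omega.csv", index=False)
        pcols = [f"{c}|{j}" for c in self.counties for j in self.clusters]
        frame(self.p_flat.reshape(self.n_draws, -1), pcols).to_csv(
            path / "p.csv", index=False, float_format="%.6g"
        )
        if not self.diagnostics.empty:
            self.diagnostics.to_csv(path / "diagnostics.csv", index=False)
        meta = {
            "counties": self.counties,
            "states": self.states,
            "clusters": [int(j) for j in self.clusters],
            "chains": int(self.n_chains),
            "kept_draws": int(self.beta.shape[1]),
            "seed": int(self.seed),
            "has_omega": self.omega is not None,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        nch, nd = meta["chains"], meta["kept_draws"]
        C, J = len(meta["counties"]), len(meta["clusters"])

        def unflat(df, shape):
            return df.drop(columns="chain").to_numpy(dtype=float).reshape((nch, nd) + shape)

        beta = unflat(pd.read_csv(path / "beta.csv"), (J,))
        scal = pd.read_csv(path / "scalars.csv")
        dev = unflat(scal[["chain", "deviance"]], ())
        lsm = (
            unflat(scal[["chain", "log_sigma_mu"]], ())
            if "log_sigma_mu" in scal
            else None
        )
        lsv = (
            unflat(scal[["chain", "log_sigma_v"]], ())
            if "log_sigma_v" in scal
            else None
        )
        omega = (
            unflat(pd.read_csv(path / "omega.csv"), (C,)) if meta["has_omega"] else None
        )
        p = unflat(pd.read_csv(path / "p.csv"), (C * J,)).reshape(nch, nd, C, J)
        diag_path = path / "diagnostics.csv"
        diag = pd.read_csv(diag_path) if diag_path.exists() else pd.DataFrame()
        return cls(
            beta=beta,
            p=p,
            deviance=dev,
            log_sigma_mu=lsm,
            log_sigma_v=lsv,
            omega=omega,
            counties=meta["counties"],
            states=meta["states"],
            clusters=meta["clusters"],
            seed=meta["seed"],
            diagnostics=diag,
        )


def conjugate_oracle(
    y_eff: float,
    n: float,
    hist: Sequence[tuple[float, float]] = (),
    alpha0: float = 1.0,
    a: float = 1.0,
    b: float = 1.0,
) -> tuple[float, float]:
    """Closed-form posterior for the single-cell conjugate reduction.

    With a Beta(a, b) prior on a single cell probability p, a current
    count y_eff of n, and historical (Y0, n0) pairs tempered by alpha0,
    the posterior is

        Beta(a + y_eff + alpha0 * sum Y0,
             b + (n - y_eff) + alpha0 * sum (n0 - Y0)).

    No covariates, random effects, or zero inflation: this is the ground
    truth the MCMC is checked against, never the production estimator.
    """
    a_post = a + y_eff + alpha0 * sum(Y0 for Y0, _ in hist)
    b_post = b + (n - y_eff) + alpha0 * sum(n0 - Y0 for Y0, n0 in hist)
    return float(a_post), float(b_post)


def initialize_state(
    model: PrevalenceModel, seed: int = 0, jitter: float = 0.0
) -> ParameterState:
    """Data-informed starting point with a finite log-posterior.

    beta_j starts at the empirical logit of the pooled cluster rate
    (0.5-continuity corrected so all-zero clusters stay finite), random
    effects at zero, both scales at 0.5, and logit(omega_i) at the
    county's observed fraction of all-zero data cells shrunk into
    (0.01, 0.99).
    """
    rng = np.random.default_rng(seed)
    n_j = model.n.sum(axis=0)
    y_j = model.y.sum(axis=0)
    rate = (y_j + 0.5) / (n_j + 1.0)
    beta = logit(np.clip(rate, 1e-6, 1 - 1e-6))
    u_mu = np.zeros((model.C, model.J))
    u_v = np.zeros((model.S, model.J))
    logit_om = None
    if model.spec.use_zero_inflation:
        with np.errstate(invalid="ignore"):
            frac = np.where(
                model.mask.sum(axis=1) > 0,
                ((model.y_raw == 0) & model.mask).sum(axis=1)
                / np.maximum(model.mask.sum(axis=1), 1),
                0.5,
            )
        logit_om = logit(np.clip(frac, 0.01, 0.99))
    state = ParameterState(
        beta=beta,
        u_mu=u_mu,
        u_v=u_v,
        log_sigma_mu=float(np.log(0.5)),
        log_sigma_v=float(np.log(0.5)),
        logit_omega=logit_om,
        gamma=np.zeros(model.n_covariates),
    )
    if jitter > 0:
        state.beta = state.beta + jitter * rng.standard_normal(model.J)
        if model.spec.include_county_re:
            state.u_mu = jitter * rng.standard_normal((model.C, model.J))
        if model.spec.include_state_re:
            state.u_v = jitter * rng.standard_normal((model.S, model.J))
        if state.logit_omega is not None:
            state.logit_omega = state.logit_omega + jitter * rng.standard_normal(model.C)
    return state


class _Chain:
    """One chain of the blocked Metropolis-within-Gibbs sampler."""

    def __init__(self, model: PrevalenceModel, state: ParameterState, rng):
        self.m = model
        self.st = state
        self.rng = rng
        self.eta = model.linear_predictor(state)
        self.cll = model.cell_loglik(self.eta, state.omega)
        # log step sizes per block
        self.steps = {
            "u_mu": np.log(0.8),
            "u_v": np.log(0.8),
            "beta": np.log(0.3),
            "omega": np.log(0.8),
            "sigma_mu": np.log(0.3),
            "sigma_v": np.log(0.3),
            "gamma": np.log(0.1),
        }

    def _adapt(self, name: str, acc_rate: float, it: int):
        gain = (it + 10.0) ** -0.6
        self.steps[name] += gain * (acc_rate - _ACCEPT_TARGET)
        self.steps[name] = float(np.clip(self.steps[name], -8.0, 3.0))

    def _metropolis_matrix(self, delta, shape):
        return np.log(self.rng.uniform(size=shape)) < delta

    def sweep(self, it: int, adapting: bool):
        m, st, rng = self.m, self.st, self.rng
        om = st.omega

        if m.spec.include_county_re:
            s = np.exp(self.steps["u_mu"])
            prop = st.u_mu + s * rng.standard_normal((m.C, m.J))
            eta_p = self.eta + st.sigma_mu * (prop - st.u_mu)
            cll_p = m.cell_loglik(eta_p, om)
            delta = cll_p - self.cll + 0.5 * (st.u_mu**2 - prop**2)
            acc = self._metropolis_matrix(delta, (m.C, m.J))
            st.u_mu = np.where(acc, prop, st.u_mu)
            self.eta = np.where(acc, eta_p, self.eta)
            self.cll = np.where(acc, cll_p, self.cll)
            if adapting:
                self._adapt("u_mu", float(acc.mean()), it)

        if m.spec.include_state_re:
            s = np.exp(self.steps["u_v"])
            prop = st.u_v + s * rng.standard_normal((m.S, m.J))
            eta_p = self.eta + st.sigma_v * (prop - st.u_v)[m.state_of_county]
            cll_p = m.cell_loglik(eta_p, om)
            dcell = cll_p - self.cll
            dsj = np.zeros((m.S, m.J))
            np.add.at(dsj, m.state_of_county, dcell)
            delta = dsj + 0.5 * (st.u_v**2 - prop**2)
            acc = self._metropolis_matrix(delta, (m.S, m.J))
            acc_c = acc[m.state_of_county]
            st.u_v = np.where(acc, prop, st.u_v)
            self.eta = np.where(acc_c, eta_p, self.eta)
            self.cll = np.where(acc_c, cll_p, self.cll)
            if adapting:
                self._adapt("u_v", float(acc.mean()), it)

        # fixed effects beta_j
        s = np.exp(self.steps["beta"])
        prop = st.beta + s * rng.standard_normal(m.J)
        eta_p = self.eta + (prop - st.beta)[None, :]
        cll_p = m.cell_loglik(eta_p, om)
        delta = (cll_p - self.cll).sum(axis=0) + self._beta_prior_delta(st.beta, prop)
        acc = self._metropolis_matrix(delta, (m.J,))
        acc_c = np.broadcast_to(acc, (m.C, m.J))
        st.beta = np.where(acc, prop, st.beta)
        self.eta = np.where(acc_c, eta_p, self.eta)
        self.cll = np.where(acc_c, cll_p, self.cll)
        if adapting:
            self._adapt("beta", float(acc.mean()), it)

        if m.n_covariates:
            s = np.exp(self.steps["gamma"])
            prop = st.gamma + s * rng.standard_normal(m.n_covariates)
            eta_p = self.eta + m.covariates @ (prop - st.gamma)
            cll_p = m.cell_loglik(eta_p, om)
            delta = float((cll_p - self.cll).sum()) + 0.5 * float(
                ((st.gamma / m.spec.prior_fixed_sd) ** 2).sum()
                - ((prop / m.spec.prior_fixed_sd) ** 2).sum()
            )
            if np.log(rng.uniform()) < delta:
                st.gamma, self.eta, self.cll = prop, eta_p, cll_p
                acc_rate = 1.0
            else:
                acc_rate = 0.0
            if adapting:
                self._adapt("gamma", acc_rate, it)

        if m.spec.use_zero_inflation:
            s = np.exp(self.steps["omega"])
            prop = st.logit_omega + s * rng.standard_normal(m.C)
            cll_p = m.cell_loglik(self.eta, expit(prop))
            sd = m.spec.prior_omega_logit_sd
            delta = (cll_p - self.cll).sum(axis=1) + 0.5 * (
                st.logit_omega**2 - prop**2
            ) / sd**2
            acc = self._metropolis_matrix(delta, (m.C,))
            st.logit_omega = np.where(acc, prop, st.logit_omega)
            rows = acc[:, None]
            self.cll = np.where(rows, cll_p, self.cll)
            om = st.omega
            if adapting:
                self._adapt("omega", float(acc.mean()), it)

        if m.spec.include_county_re:
            self._scale_update("sigma_mu", st.u_mu, om, it, adapting)
        if m.spec.include_state_re:
            self._scale_update("sigma_v", st.u_v[m.state_of_county], om, it, adapting, state_level=True)

    def _beta_prior_delta(self, cur, prop):
        spec = self.m.spec
        if spec.beta_prior_beta is not None:
            from scipy.special import log_expit

            a, b = spec.beta_prior_beta
            return (
                a * (log_expit(prop) - log_expit(cur))
                + b * (log_expit(-prop) - log_expit(-cur))
            )
        return 0.5 * (cur**2 - prop**2) / spec.prior_fixed_sd**2

    def _scale_update(self, name, u_county, om, it, adapting, state_level=False):
        m, st, rng = self.m, self.st, self.rng
        attr = "log_sigma_mu" if name == "sigma_mu" else "log_sigma_v"
        t = getattr(st, attr)
        s = np.exp(self.steps[name])
        t_p = t + s * rng.standard_normal()
        eta_p = self.eta + (np.exp(t_p) - np.exp(t)) * u_county
        cll_p = m.cell_loglik(eta_p, om)
        scale = m.spec.prior_re_scale
        lp_cur = -0.5 * (np.exp(t) / scale) ** 2 + t
        lp_prop = -0.5 * (np.exp(t_p) / scale) ** 2 + t_p
        delta = float((cll_p - self.cll).sum()) + lp_prop - lp_cur
        if np.log(rng.uniform()) < delta:
            setattr(st, attr, float(t_p))
            self.eta, self.cll = eta_p, cll_p
            acc = 1.0
        else:
            acc = 0.0
        if adapting:
            self._adapt(name, acc, it)


def _compute_diagnostics(draws: PosteriorDraws, model: PrevalenceModel) -> pd.DataFrame:
    import arviz as az

    data = {"beta": draws.beta}
    if draws.log_sigma_mu is not None:
        data["log_sigma_mu"] = draws.log_sigma_mu
    if draws.log_sigma_v is not None:
        data["log_sigma_v"] = draws.log_sigma_v
    if draws.omega is not None:
        data["omega"] = draws.omega
    # cell probabilities restricted to cells with data
    mask_idx = np.argwhere(model.mask)
    if len(mask_idx):
        data["p"] = draws.p[:, :, mask_idx[:, 0], mask_idx[:, 1]]
    idata = az.from_dict(posterior=data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for var in data:
        r = np.atleast_1d(np.asarray(rhat[var]))
        e = np.atleast_1d(np.asarray(ess[var]))
        for k, (rv, ev) in enumerate(zip(r.ravel(), e.ravel())):
            if var == "beta":
                label = f"beta[{model.clusters[k]}]"
            elif var == "omega":
                label = f"omega[{model.counties[k]}]"
            elif var == "p":
                i, j = mask_idx[k]
                label = f"p[{model.counties[i]}|{model.clusters[j]}]"
            else:
                label = var
            rows.append({"parameter": label, "rhat": float(rv), "ess": float(ev)})
    return pd.DataFrame(rows)


def run_mcmc(
    model: PrevalenceModel,
    settings: McmcSettings | None = None,
    progress: bool = False,
    compute_diagnostics: bool = True,
) -> PosteriorDraws:
    """Sample the joint posterior; deterministic given (inputs, seed).

    Each chain gets its own child seed.  If the initial state has a
    non-finite log-posterior it is re-drawn with jitter up to five times
    before failing with a diagnostic dump.
    """
    if settings is None:
        settings = McmcSettings()
    nch, nwarm, nkeep = settings.chains, settings.warmup_draws, settings.kept_draws
    C, J = model.C, model.J
    zi = model.spec.use_zero_inflation

    beta_out = np.empty((nch, nkeep, J))
    p_out = np.empty((nch, nkeep, C, J))
    dev_out = np.empty((nch, nkeep))
    lsm_out = np.empty((nch, nkeep)) if model.spec.include_county_re else None
    lsv_out = np.empty((nch, nkeep)) if model.spec.include_state_re else None
    om_out = np.empty((nch, nkeep, C)) if zi else None

    for ch in range(nch):
        rng = np.random.default_rng(np.random.SeedSequence(settings.seed, spawn_key=(ch,)))
        state = None
        for attempt in range(6):
            cand = initialize_state(
                model, seed=settings.seed * 1000 + ch * 7 + attempt,
                jitter=0.0 if attempt == 0 else 0.1 * attempt,
            )
            if np.isfinite(model.log_posterior(cand)):
                state = cand
                break
        if state is None:
            raise RuntimeError(
                "could not find a finite initial log-posterior after 6 attempts; "
                f"last log-posterior {model.log_posterior(cand)!r}"
            )
        chain = _Chain(model, state, rng)
        for it in range(nwarm):
            chain.sweep(it, adapting=True)
        # resync cached quantities after warmup drift
        chain.eta = model.linear_predictor(chain.st)
        chain.cll = model.cell_loglik(chain.eta, chain.st.omega)
        for it in range(nkeep):
            chain.sweep(it, adapting=False)
            st = chain.st
            beta_out[ch, it] = st.beta
            p = expit(chain.eta)
            p_out[ch, it] = p
            om = st.omega
            dev_out[ch, it] = model.deviance(p, om)
            if lsm_out is not None:
                lsm_out[ch, it] = st.log_sigma_mu
            if lsv_out is not None:
                lsv_out[ch, it] = st.log_sigma_v
            if zi:
                om_out[ch, it] = om
        if progress:
            print(f"chain {ch + 1}/{nch} done")

    draws = PosteriorDraws(
        beta=beta_out,
        p=p_out,
        deviance=dev_out,
        log_sigma_mu=lsm_out,
        log_sigma_v=lsv_out,
        omega=om_out,
        counties=list(model.counties),
        states=list(model.states),
        clusters=list(model.clusters),
        seed=settings.seed,
    )
    if compute_diagnostics:
        draws.diagnostics = _compute_diagnostics(draws, model)
    return draws
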