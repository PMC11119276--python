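"""Posterior results: county prevalence aggregation and fit summaries.

County prevalence is the population-projection-weighted mean of the cell
probabilities,

    p_i = sum_j p_ij N_ij / sum_j N_ij,

computed *per posterior draw* so that credible intervals propagate the
full joint uncertainty.  For zero-inflated models a second, predictive
view of the same posterior is available: the realized county prevalence
is 0 with probability omega_i (a structural-zero county has no cases to
find) and p_i otherwise, so its posterior is a mixture with weight
omega_i at zero.  Its equal-tailed intervals are computed as weighted
quantiles over draws — deterministically, with no extra Monte Carlo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import McmcSettings, PosteriorDraws


def _weighted_interval(values, weights, lo=0.025, hi=0.975):
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    return float(v[np.searchsorted(cw, lo)]), float(v[np.searchsorted(cw, hi)])


def county_prevalence(
    draws: PosteriorDraws,
    population: pd.DataFrame,
    predictive: bool = False,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate posterior cell probabilities to county prevalence.

    Parameters
    ----------
    draws
        Posterior draws (all counties present in the fit are estimated,
        including counties whose p_ij come purely from the hierarchy).
    population
        County x cluster projection table with columns
        (county, cluster, population); must cover every cluster of every
        estimated county.
    predictive
        With zero inflation, summarize the realized prevalence (mixture
        with mass omega_i at zero) instead of the latent aggregation
        p_i.  Without zero inflation the two coincide.
    cells
        Optional CellTable used only to fill the ``had_data`` flag.

    Returns a frame with columns county, mean, ci_low, ci_high, n_draws,
    had_data.
    """
    counties, clusters = draws.counties, draws.clusters
    wide = (
        population.pivot(index="county", columns="cluster", values="population")
        .reindex(index=counties, columns=clusters)
    )
    missing = {
        c: [int(j) for j in wide.columns[wide.loc[c].isna()]]
        for c in counties
        if wide.loc[c].isna().any()
    }
    if missing:
        raise ValueError(f"population table missing (county: clusters): {missing}")
    N = wide.to_numpy(dtype=float)
    if np.any(N <= 0):
        raise ValueError("population projections must be positive")

    p = draws.p_flat                      # (D, C, J)
    agg = (p * N).sum(axis=2) / N.sum(axis=1)   # (D, C)
    D = agg.shape[0]

    if predictive and draws.omega is not None:
        om = draws.omega_flat             # (D, C)
        mean = ((1.0 - om) * agg).mean(axis=0)
        ci = np.empty((len(counties), 2))
        for c in range(len(counties)):
            vals = np.concatenate([[0.0], agg[:, c]])
            wts = np.concatenate([[om[:, c].sum()], 1.0 - om[:, c]])
            ci[c] = _weighted_interval(vals, wts)
    else:
        mean = agg.mean(axis=0)
        ci = np.column_stack(
            [np.quantile(agg, 0.025, axis=0), np.quantile(agg, 0.975, axis=0)]
        )

    if cells is not None:
        nn = cells.groupby("county")["n"].sum()
        had = pd.Series(counties).map(nn).fillna(0).to_numpy() > 0
    else:
        had = np.full(len(counties), True)

    out = pd.DataFrame(
        {
            "county": counties,
            "mean": mean,
            "ci_low": np.minimum(ci[:, 0], mean),
            "ci_high": np.maximum(ci[:, 1], mean),
            "n_draws": D,
            "had_data": had,
        }
    )
    return out


def county_prevalence_draws(draws: PosteriorDraws, population: pd.DataFrame) -> np.ndarray:
    """Per-draw latent county prevalence matrix (draws x counties)."""
    wide = (
        population.pivot(index="county", columns="cluster", values="population")
        .reindex(index=draws.counties, columns=draws.clusters)
    )
    N = wide.to_numpy(dtype=float)
    if np.isnan(N).any():
        raise ValueError("population table does not cover all (county, cluster) cells")
    return (draws.p_flat * N).sum(axis=2) / N.sum(axis=1)


class PrevalenceResults:
    """Fitted-model results: draws, prevalence estimates, DIC, summary."""

    def __init__(self, model, draws: PosteriorDraws, settings: McmcSettings):
        self.model = model
        self.draws = draws
        self.settings = settings

    # ------------------------------------------------------------ estimates

    def county_prevalence(self, population, predictive: bool = False) -> pd.DataFrame:
        out = county_prevalence(self.draws, population, predictive=predictive)
        out["had_data"] = self.model.mask.sum(axis=1) > 0
        return out

    def point_estimates(self, population, predictive: bool = True) -> pd.Series:
        """Posterior-mean county prevalence as a Series indexed by county."""
        est = self.county_prevalence(population, predictive=predictive)
        return est.set_index("county")["mean"]

    # ----------------------------------------------------------------- fit

    @property
    def p_mean(self) -> np.ndarray:
        return self.draws.p_flat.mean(axis=0)

    @property
    def omega_mean(self) -> np.ndarray | None:
        if self.draws.omega is None:
            return None
        return self.draws.omega_flat.mean(axis=0)

    def dic(self) -> float:
        """Deviance information criterion, 2 * mean(D) - D(posterior mean)."""
        from .validation import dic as _dic

        d_at_mean = self.model.deviance(self.p_mean, self.omega_mean)
        return _dic(self.draws.deviance_flat, d_at_mean)

    def convergence_failures(self) -> pd.DataFrame:
        return self.draws.convergence_failures(
            self.settings.target_rhat, self.settings.min_ess
        )

    def summary(self) -> str:
        d = self.draws
        lines = [
            f"{self.model.spec.variant_name} prevalence model",
            "=" * 40,
            f"counties: {self.model.C}   states: {self.model.S}   clusters: {self.model.J}",
            f"chains: {d.n_chains}   kept draws/chain: {d.beta.shape[1]}   seed: {d.seed}",
            f"DIC: {self.dic():.2f}",
        ]
        if d.log_sigma_mu is not None:
            sm = np.exp(d._flat(d.log_sigma_mu))
            lines.append(f"sigma_mu: {sm.mean():.3f} (sd {sm.std():.3f})")
        if d.log_sigma_v is not None:
            sv = np.exp(d._flat(d.log_sigma_v))
            lines.append(f"sigma_v:  {sv.mean():.3f} (sd {sv.std():.3f})")
        bm = d.beta_flat.mean(axis=0)
        bs = d.beta_flat.std(axis=0)
        lines.append("cluster fixed effects (posterior mean +/- sd):")
        for j, m, s in zip(d.clusters, bm, bs):
            lines.append(f"  beta[{j}]: {m:+.3f} +/- {s:.3f}")
        if not d.diagnostics.empty:
            lines.append(
                f"max rhat: {d.diagnostics['rhat'].max():.4f}   "
                f"min ess: {d.diagnostics['ess'].min():.0f}"
            )
            bad = self.convergence_failures()
            if len(bad):
                lines.append(f"convergence flags: {len(bad)} parameter(s)")
        return "\n".join(lines)

    def plot_prevalence(self, population, ax=None, predictive: bool = False):
        """Caterpillar plot of county prevalence with 95% intervals."""
        import matplotlib.pyplot as plt

        est = self.county_prevalence(population, predictive=predictive)
        est = est.sort_values("mean").reset_index(drop=True)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.15 * len(est) + 1))
        ax.errorbar(
            est["mean"],
            np.arange(len(est)),
            xerr=[est["mean"] - est["ci_low"], est["ci_high"] - est["mean"]],
            fmt="o",
            ms=2,
            lw=0.6,
        )
        ax.set_yticks(np.arange(len(est)))
        ax.set_yticklabels(est["county"], fontsize=5)
        ax.set_xlabel("prevalence")
        return ax
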