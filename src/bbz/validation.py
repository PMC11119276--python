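"""Model-comparison and agreement statistics.

Given per-county estimates p_i and a per-county reference p_ref_i (in the
original study the reference role is played by a large direct-estimate
survey; in tests by the synthetic generator's truth), this module
computes RMSE, mean bias error (MBE), the deviance information criterion
(DIC), Bland-Altman limits of agreement, and bias stratified by each
county's level of "zero" counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZERO_LEVEL_BINS = ((0.0, 0.7), (0.7, 0.9), (0.9, 1.0))
ZERO_LEVEL_LABELS = ("0-<70%", "70-<90%", "90-<100%", "100%")


def _align(est, ref):
    est = pd.Series(est, dtype=float)
    ref = pd.Series(ref, dtype=float)
    if not isinstance(est.index, pd.RangeIndex) or not isinstance(ref.index, pd.RangeIndex):
        sym = set(est.index).symmetric_difference(ref.index)
        if sym:
            raise ValueError(f"county sets differ; symmetric difference: {sorted(sym)}")
        ref = ref.reindex(est.index)
    elif len(est) != len(ref):
        raise ValueError(f"length mismatch: {len(est)} vs {len(ref)}")
    if len(est) == 0:
        raise ValueError("need at least one county")
    return est.to_numpy(), ref.to_numpy()


def rmse(est, ref) -> float:
    """Root mean square error sqrt(mean((p_i - p_ref_i)^2))."""
    e, r = _align(est, ref)
    return float(np.sqrt(np.mean((e - r) ** 2)))


def mbe(est, ref) -> float:
    """Mean bias error mean(p_i - p_ref_i); sign preserved."""
    e, r = _align(est, ref)
    return float(np.mean(e - r))


def dic(deviance_draws, deviance_at_posterior_mean: float) -> float:
    """2 * (posterior mean deviance) - (deviance at the posterior mean)."""
    d = np.asarray(deviance_draws, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 deviance draws")
    if not np.all(np.isfinite(d)):
        bad = np.where(~np.isfinite(d))[0]
        raise ValueError(f"non-finite deviance at draw indices {bad[:10].tolist()}")
    return float(2.0 * d.mean() - deviance_at_posterior_mean)


@dataclass
class BlandAltman:
    mean_bias: float
    lower95: float
    upper95: float
    pairs: pd.DataFrame  # columns: county (if known), mean, diff


def bland_altman(est, ref) -> BlandAltman:
    """Limits-of-agreement analysis of paired estimates.

    diff_i = est_i - ref_i against mean_i = (est_i + ref_i) / 2, with
    95% limits mean_bias +/- 1.96 * SD(diff).  Requires at least three
    pairs.  The SD uses the n-1 denominator.
    """
    e, r = _align(est, ref)
    if len(e) < 3:
        raise ValueError("Bland-Altman analysis needs at least 3 paired counties")
    diff = e - r
    avg = (e + r) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pairs = pd.DataFrame({"mean": avg, "diff": diff})
    if isinstance(est, pd.Series) and not isinstance(est.index, pd.RangeIndex):
        pairs.insert(0, "county", list(est.index))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, pairs)


def county_zero_levels(cells: pd.DataFrame) -> pd.Series:
    """Fraction of each county's sampled cells (n > 0) with zero cases.

    Counties with no sampled cells at all are excluded (their zero level
    is undefined).
    """
    with_data = cells[cells["n"] > 0]
    return with_data.groupby("county").apply(
        lambda g: float((g["y"] == 0).mean()), include_groups=False
    )


def zero_level_stratum(level: float) -> str:
    """Bin a zero level into the four printed strata (left-closed bins,
    with 100% its own singleton)."""
    if level >= 1.0:
        return ZERO_LEVEL_LABELS[3]
    for (lo, hi), label in zip(ZERO_LEVEL_BINS, ZERO_LEVEL_LABELS):
        if lo <= level < hi:
            return label
    raise ValueError(f"zero level outside [0, 1]: {level}")


def zero_level_strata(cells: pd.DataFrame, bias) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify per-county bias by the county's zero-count level.

    Parameters
    ----------
    cells
        CellTable for the analyzed year.
    bias
        Per-county bias (est - ref), a Series indexed by county.

    Returns
    -------
    assignments
        One row per county: county, zero_level, stratum, bias.
    summary
        Per-stratum box-plot statistics (n, median, q1, q3, whiskers);
        empty strata appear with n = 0.
    """
    bias = pd.Series(bias, dtype=float)
    levels = county_zero_levels(cells)
    common = [c for c in bias.index if c in levels.index]
    assignments = pd.DataFrame(
        {
            "county": common,
            "zero_level": [levels[c] for c in common],
            "bias": [bias[c] for c in common],
        }
    )
    assignments["stratum"] = assignments["zero_level"].map(zero_level_stratum)

    rows = []
    for label in ZERO_LEVEL_LABELS:
        b = assignments.loc[assignments["stratum"] == label, "bias"].to_numpy()
        if len(b) == 0:
            rows.append({"stratum": label, "n": 0})
            continue
        q1, med, q3 = np.percentile(b, [25, 50, 75])
        iqr = q3 - q1
        lo_w = b[b >= q1 - 1.5 * iqr].min()
        hi_w = b[b <= q3 + 1.5 * iqr].max()
        rows.append(
            {
                "stratum": label,
                "n": len(b),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": lo_w,
                "whisker_high": hi_w,
            }
        )
    return assignments, pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """All comparison statistics for one fitted model."""

    model_name: str
    rmse: float
    mbe: float
    dic: float
    bland_altman: BlandAltman | None = None
    zero_level_summary: pd.DataFrame | None = None
    zero_level_assignments: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "model_name": self.model_name,
            "rmse": self.rmse,
            "mbe": self.mbe,
            "dic": self.dic,
        }
        if self.bland_altman is not None:
            out["bland_altman"] = {
                "mean_bias": self.bland_altman.mean_bias,
                "lower95": self.bland_altman.lower95,
                "upper95": self.bland_altman.upper95,
            }
        if self.zero_level_summary is not None:
            out["zero_level_summary"] = self.zero_level_summary.to_dict(orient="records")
        out.update(self.extra)
        return out


def validate_fit(
    results,
    reference: pd.Series,
    population: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    predictive: bool = True,
) -> ValidationReport:
    """Score a fitted model against a per-county reference.

    Point estimates are posterior means of the realized county
    prevalence (``predictive=True`` includes the structural-zero mass of
    zero-inflated models; models without zero inflation are unaffected).
    Only counties present in ``reference`` are scored.
    """
    est = results.point_estimates(population, predictive=predictive)
    common = [c for c in est.index if c in reference.index]
    if not common:
        raise ValueError("no counties shared between estimates and reference")
    e = est.loc[common]
    r = pd.Series(reference).loc[common].astype(float)
    ba = bland_altman(e, r) if len(common) >= 3 else None
    strata = None
    assign = None
    if cells is not None:
        assign, strata = zero_level_strata(cells, e - r)
    return ValidationReport(
        model_name=results.model.spec.variant_name,
        rmse=rmse(e, r),
        mbe=mbe(e, r),
        dic=results.dic(),
        bland_altman=ba,
        zero_level_summary=strata,
        zero_level_assignments=assign,
    )


def plot_bland_altman(ba: BlandAltman, ax=None):
    """Scatter of per-county bias against pair means with 95% limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.pairs["mean"], ba.pairs["diff"], s=8)
    for yv, style in ((ba.mean_bias, "-"), (ba.lower95, "--"), (ba.upper95, "--")):
        ax.axhline(yv, ls=style, color="gray")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("mean of estimate and reference")
    ax.set_ylabel("bias (estimate - reference)")
    return ax
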