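# Methods

## Model

The estimand is county-level prevalence of a rare binary condition from
one year of a state-level survey.  Respondents are cross-classified into
12 demographic clusters (age 18–24 / 25–29 / 30–35 × male / female ×
white / non-white); the fixed cluster→index mapping is lexicographic
(age slowest, race fastest) so results are reproducible across runs.

Cell counts follow a hierarchical logit-binomial model,

    y_ij ~ Binomial(n_ij, p_ij),
    logit(p_ij) = β_j + Zγ + μ_ij + v_{s(i)j},

with independent county effects μ_ij ~ N(0, σ_μ²) and state effects
v_sj ~ N(0, σ_v²).  Three optional features produce the four variants
BHBI / BZBI / BPLW / BBZ:

* **Sampling weights.**  The likelihood fits the effective count
  y_eff = n · Σ(log w_k)^T y_k / Σ(log w_k)^T instead of y.  The final
  multiplier is n (the cell sample size): this makes T = 0 reproduce the
  raw counts exactly, which is the defining property of the unweighted
  limit; a `literal_eq34` option rescales by y instead, for auditing a
  variant of the formula seen in print whose T = 0 limit is y²/n.
  Weights must exceed 1 so log w > 0 (expansion weights in practice are
  ≫ 1); records with w ≤ 1 are rejected at read time.  Default T = 1
  (fully weighted); no principled selection rule for T is built in.
  Because y_eff is generally non-integer, the binomial coefficient is
  computed through log-Gamma; for integer y this is the exact log-pmf.
  Historical years use the same T (symmetry of the construction).

* **Power prior.**  Each historical year's cell contributes
  α₀ · log L(Y0_ij | p_ij), evaluated at the *current* cell probability —
  the standard power-prior construction, consistent with the single-cell
  conjugate posterior Beta(a + y + α₀ΣY0, b + (n−y) + α₀Σ(n0−Y0)).
  Multiple years share one α₀ (default 0.5).  α₀ → 0 ignores history;
  α₀ = 1 pools it fully.

* **Zero inflation.**  Each cell's likelihood is the mixture
  ω_i + (1−ω_i)(1−p)^n at y = 0 and (1−ω_i)·Binomial otherwise, with the
  mixing weight ω_i shared within a county.  The discrete indicator is
  marginalized analytically, so the sampled posterior is smooth.

## Priors

β_j, γ ~ N(0, sd 1000): flat on the logit scale.  σ_μ, σ_v ~
Half-Normal(1): weakly informative, standard for logit-scale
hierarchies.  logit(ω_i) ~ N(0, 1.8), which is close to uniform on
ω ∈ (0, 1).  We deliberately do *not* put the sd-1000 "non-informative"
normal on logit(ω): on the probability scale that is a bathtub density
concentrating all mass on {0, 1} — highly informative in the wrong way,
and poison for mixing.  Near-uniform on ω is the faithful reading of a
non-informative intent for a probability parameter.

## Inference

Sampling is adaptive Metropolis-within-Gibbs, exploiting the model's
conditional-independence structure: given (β, σ, v), the standardized
county effects u_μ[i,j] are independent across cells, so all C×J of them
are updated simultaneously with vectorized single-site random-walk
proposals; likewise v across (state, cluster) pairs, β across clusters,
and logit ω across counties, with scalar updates for the two log-scales.
Random effects are non-centered (μ = σ_μ·u) to avoid funnel geometry.
Per-block step sizes adapt toward 44% acceptance during warmup
(Robbins–Monro, gain (t+10)^-0.6) and are frozen afterwards, so the kept
draws form a time-homogeneous chain.  Defaults: 4 chains × 1000 warmup ×
1000 kept; every reported estimate requires ≥ 200 kept draws per chain.
R-hat and ESS are computed per scalar parameter via arviz; a fit is
flagged (not rejected) when R-hat > 1.01 or ESS < 200.

Correctness anchor: with random effects off and a Beta(a,b)-induced
prior on expit(β), the single-cell model has the closed-form conjugate
posterior above; the sampler is required (in tests) to match its mean
within 3 Monte-Carlo standard errors across randomized configurations,
and the full ZIB posterior was additionally cross-checked against 2-D
quadrature.  Initialization is data-informed (empirical logits with a
0.5 continuity correction; observed all-zero cell fractions for ω) and
re-drawn with jitter if the log-posterior is non-finite.

## County prevalence

p_i = Σ_j p_ij N_ij / Σ_j N_ij with census-style projections N_ij,
computed per draw before summarizing, so intervals propagate the joint
posterior; counties with no interviews are still estimated (their p_ij
come from the hierarchy) and flagged `had_data=False`.  Intervals are
95% equal-tailed.

Two views of the same posterior are offered.  The *latent* view (default)
is the aggregation above — the prevalence the survey would measure where
the condition occurs.  The *predictive* view (`predictive=True`, only
meaningful with zero inflation) is the realized prevalence: 0 with
probability ω_i (a structural-zero county has no cases), else p_i.  Its
equal-tailed interval is a deterministic weighted quantile over draws
(mass Σω/D at zero plus the aggregated draws), no extra Monte Carlo.
Point estimates used in validation are predictive means, which reduces
to the plain posterior mean for models without zero inflation.

## Validation metrics

RMSE = √(Σ(p_i − p_ref,i)²/m) and MBE = Σ(p_i − p_ref,i)/m against any
per-county reference table (a large direct-estimate survey in the
motivating application; the generator's truth in tests).
DIC = 2·mean(D) − D(posterior mean) with deviance D = −2 × log-likelihood
of the **current** year's data only — tempered historical terms are
excluded because DIC measures fit to the analyzed data.  Note that
weighted variants fit y_eff while unweighted ones fit y, so cross-variant
DIC compares fits to slightly different data; the source tables for this
class of model do the same, and we follow that convention.
Bland–Altman limits are mean bias ± 1.96·SD(diff) (n−1 SD), requiring
≥ 3 counties.  The "zero level" of a county is the fraction of its
sampled cells (n > 0) with zero cases, binned left-closed into
0–<70%, 70–<90%, 90–<100%, and exactly 100%; counties with no sampled
cells are excluded from stratification (their level is undefined).

## Synthetic generator

The generator is first-class, tested code; it emulates the data features
the model targets, at a scale chosen to keep a full four-variant
comparison in minutes on one CPU: 5 states × 20 counties × 12 clusters,
~50 respondents per county, one current plus two historical years.

* **Truth**: p_ij = expit(β_j + μ + v) with β centered near logit(0.8%)
  (the rare-disease regime), σ_μ = 0.3, σ_v = 0.2.
* **Structural zeros**: each county draws ω_i ~ Beta(mean 0.3,
  concentration 6) and a structural indicator z_i ~ Bern(ω_i);
  structural counties have p_ij ≡ 0 and emit only non-cases.  Note the
  generator's zeros are county-level while the model's mixture is
  cell-level — a deliberate, realistic mismatch.
* **Weights**: w = 1 + exp(N(2, 0.5)), guaranteeing log w > 0.
* **Informative sampling** (coupling κ, default 0.5): sampled outcomes
  are drawn at logit(p) + κ (cases oversampled) and case weights have
  their meanlog reduced by κ, i.e. weight ≈ inverse inclusion
  probability.  The unweighted estimator is therefore biased upward by a
  known direction, which the log-weight adjustment must reduce — a
  falsifiable test of the weighting feature.
* **Historical years**: drawn from the same truth with a log-odds
  `drift` (default 0, i.e. exchangeable years).
* **Pseudo-counties**: county blocks are resampled with replacement and
  case interviews thinned (or zero blocks replaced from the non-zero
  pool) until the requested fraction of zero-case pseudo-counties holds
  *exactly*; provenance to source counties is recorded.  Exactness is
  auditable; how many respondents the original construction retained is
  unknown, so our defaults are stated, not reproduced.

What the generator does not emulate: raking-style weight construction,
spatial correlation between neighbouring counties, cluster-size
imbalance beyond population shares, and item nonresponse.  Passing tests
therefore demonstrate correctness of the machinery and the direction of
the feature effects, not performance on any real survey.

## Known limitations

* At ~50 respondents per county, a zero cell carries almost no evidence
  against the structural explanation ((1−p)^4 ≈ 0.96), so the cell-level
  mixture partially "explains away" sampling zeros and the latent p
  surface is biased upward; the predictive view absorbs much of this in
  point estimates, but latent intervals are not calibrated for realized
  truth at this sample size, and predictive intervals are conservative
  (their lower bound is 0 whenever the posterior structural mass exceeds
  2.5%).  With county samples in the hundreds, zero cells become
  informative and the effect shrinks.
* The log-weight adjustment is a pragmatic bias reduction, not a
  design-consistent estimator; under strong informative sampling it
  removes only part of the bias.
* No spatial random effects; counties are exchangeable given their
  state.
* DIC uses the plug-in posterior-mean deviance and inherits DIC's usual
  caveats for mixture models.
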