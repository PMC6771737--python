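# Methods

## Model

Eleven binomial vital-rate submodels (survival of six age–sex classes,
reproduction of ewes in three age classes, twinning of yearling and adult
ewes) share a yearly latent environmental axis

    e(t) = D_t − c(t) − α_t · t − ε_t^e,

with `D_t` the log10 August population count (entered unstandardized: its
unit coefficient anchors the scale of the axis), `t` the centered year
index, and `c(t)` the climate contribution of the active variant: zero
(baseline), `β_m M_t` for a standardized scalar covariate, or
`Σ_w f_c(w) C_tw` for a functional linear term.  Multiple climate terms add.

Survival submodels except ram lambs are thresholded (flat below θ, linear
decline above); all other submodels are plain logistic regressions in
`e(t)`.  A second axis `ε_t^f` with sd fixed at 1 loads on lamb
reproduction, adult reproduction and adult twinning; `(ε_t^e, ε_t^f)` are
iid bivariate normal across years with covariance parameterized by
`(σ_e, ρ)`.

**Second-axis identifiability.** The scale of `ε^f` and its three loadings
are jointly unidentified, and so is the sign of the axis.  We fix
sd(ε^f) = 1, estimate the three loadings freely, and constrain the
adult-reproduction loading to be non-negative (prior support), which pins
the sign.

**Reproduction timing.** All submodels in year `t` are paired with `e(t)`;
no lagged pairing is applied.

## Priors

Proper, weakly informative, judged against the covariate scales of this
model rather than "unit scale":

| block | prior | rationale |
| --- | --- | --- |
| β⁰ | N(0, 10²) | non-thresholded intercepts absorb β^e·mean(e) ≈ 5–25 on the uncentered density scale |
| β^t, β^e, β^f, α_t, β_m, γ | N(0, 10²) | the axis varies over ~0.3 log10 units, so loadings of 5–10 are ordinary |
| σ_e | Half-Normal(1) | residual axis sd is a fraction of the density range |
| ρ | Uniform(−1, 1) | |
| θ | Uniform over the central 90% range of observed D_t | thresholds are only meaningful inside the visited density range |

We verified empirically that tighter N(0, 2.5²) slope priors are *not*
weakly informative here: with 30 years of data the posterior then settles
on a mode with all axis loadings roughly halved and σ_e doubled (the prior
dominates along a weakly identified (β^e, σ_e) ridge), and parameter
recovery on simulated data fails.  With sd 10 the same data recover the
generating values.

The spline coefficients γ are the values of `f_c` at the knots (value-based
"cr" parameterization), so their prior is directly a prior on the lag
function at the knots; no quadratic smoothing penalty is used — with 8
knots over 42 windows the spline is a fixed-rank regression basis and the
prior is the only regularizer.  Knots are evenly spaced over the window
index (configurable).

A testing-only prior variant replaces the normal prior on an intercept with
the logistic-Jacobian density (uniform on the probability scale), which
makes single-submodel intercept-only models exactly conjugate
(Beta-Binomial) and gives the sampler an analytic oracle.

## Sampler

In-house adaptive random-walk Metropolis-within-Gibbs (no external
inference engine); the posterior has ~100 free parameters at 30 years.
Update blocks per sweep, in fixed order:

1. per-submodel fixed effects `(β⁰, β^t, β^e, θ, β^f)` — proposed jointly
   per submodel, accepted per submodel *in parallel* (the likelihood
   factorizes over submodels given the axis and year effects);
2. the axis block (α_t and all climate coefficients jointly) against the
   full likelihood;
3. the year-effect pairs `(ε_t^e, ε_t^f)` — proposed jointly per year,
   accepted per year in parallel (likelihood factorizes over years; the
   pairs are iid a priori);
4. `(σ_e, ρ)`, which touches only prior terms.

Proposals are Gaussian with per-coordinate spreads taken from running
moment estimates and a per-block scalar scale adapted by Robbins–Monro
toward 25% (joint blocks) / 30% (pairs) acceptance.  Adaptation runs only
during burn-in and is frozen afterwards, so retained draws come from a
valid Markov chain.  Chains are a batch dimension drawing from one seeded
generator; the same batch dimension carries independent datasets (replicate
panels, cross-validation folds) through a single kernel call, which is what
makes replicate-heavy experiments tractable on one CPU.

**Initialization.** Intercepts and loadings start from a weighted
least-squares fit of the empirical logits on `[1, t, D]` per submodel
(thresholded submodels: below-median-density level for β⁰ and a
doubled-slope start for β^e), θ at the prior midpoint, year effects at
zero, σ_e at 0.2, plus per-chain N(0, 0.1) jitter with bounded retries
until the log posterior is finite.  Starting the fixed effects at zero
instead was tried and rejected: chains then enter a funnel in which the
year effects absorb the axis signal and very long runs stay on the wrong
mode.

**Chain protocols.**  `paper_profile()`: 2 chains, burn-in 1e5, 6e6
iterations thinned by 2000 (6000 retained).  `desk_profile()`: 3 chains,
burn-in 1e4, 5e4 iterations thinned by 25 (also 6000 retained), which is
what the worked example and the test suite use (the test suite trims to
2 chains and adjusts burn-in to fit its time budget; every such profile is
stated inline).  Convergence is summarized by split-Rhat and effective
sample size per parameter (computed with arviz), flagging Rhat > 1.05;
zero-variance parameters are reported as degenerate rather than failing.

## Cross-validation

Whole years are the cross-validation clusters.  For each held-out year the
model is refitted on the remaining years (the held-out year's density and
climate stay available as covariates; its temporal covariate uses the
training panel's centering) and the marginal predictive density is
estimated by Monte Carlo over `S` posterior draws times `M` fresh
`(ε^e, ε^f)` draws from the fitted covariance, with the log computed by
log-sum-exp over all `S·M` likelihood values; the 11 submodel likelihoods
multiply, binomial coefficients included, so elpd values are proper log
predictive masses comparable across models.  The Monte-Carlo standard error
per year comes from the delta method on the sampled likelihoods and adds in
quadrature.  Refits whose split-Rhat exceeds 1.05 (or whose sampler reports
acceptance collapse) are flagged in the result, never silently dropped.
Model pairs are compared as `−2(elpd_A − elpd_B)`; negative favours A.

## Bayesian R² of the first axis

Per retained draw, `R² = Var_years(fixed) / (Var_years(fixed) + σ_e²)`
where `fixed = D_t − c(t) − α_t t` and the variance across years uses
ddof 1; reported as posterior median and 95% interval.  The residual term
is the first-axis year-effect variance only (the second axis concerns the
fecundity submodels, not the axis decomposition).  A fixed part constant
across years makes R² undefined and raises.

## Posterior predictive checks

For each retained draw (subsampled to `n_rep`), one replicate panel is
simulated from the draw's probabilities (with its fitted year effects), and
each cell's tail probability `Pr(replicate ≥ observed)` is estimated over
the replicates.  Cells outside [0.025, 0.975] are flagged; zero-trial cells
are excluded (reported as NaN).  With discrete counts the flag rate under a
well-specified model sits slightly *below* the nominal 5%, more so in
small-count submodels (yearling twinning).

## Synthetic-data generator

The generator states a fully known world and is the basis of every
stochastic test:

- **Density**: exogenous mean-reverting AR(1) on the log10 scale, stationary
  mean 2.78 (≈600 animals, giving ≈100 trials per survival class with the
  default 1/6 class fractions), stationary sd 0.12, AR coefficient 0.6.  No
  feedback from simulated survival — the inferential model conditions on
  density.  Populations below 30 are rejected.
- **Daily weather**: seasonal cosine (amplitude 6, peak mid-July) + a shared
  anomaly per 14-day block (sd 0.6) + daily noise (sd 2), with 2% of days
  missing at random.  Block-constant anomalies make the interannual window
  signal well defined while daily noise and gaps exercise the interpolation
  and aggregation steps.
- **Axes**: `(ε^e, ε^f)` drawn from the stated bivariate normal
  (σ_e = 0.1, ρ = 0.3); the FLM truth is evaluated on the *aggregated,
  centered* climate matrix produced by the package's own preprocessing, so
  the generating climate effect is exactly expressible in the fitted model.
- **Truth parameters**: below-threshold survival 0.8–0.93, thresholded
  loadings 6–9 (reproducing crash-like survival collapse over ~0.2 density
  units), thresholds 2.78–2.84, fecundity loadings 1–2.5 with intercepts
  absorbing β^e·mean(e), no submodel-level trends (the trend lives in the
  axis, α_t = 0.02), second-axis loadings (0.8, 0.5, 0.5).
- **Trial counts**: survival trials are `round(N_t/6)` per class;
  reproduction trials are the surviving female count of the class; twinning
  trials are the successful reproducers — so yearling twinning shows the
  realistic near-zero-count behaviour.
- **Default lag function**: two smooth lobes expressed in the 8-knot basis
  (γ = [0, .05, .08, 0, −.07, −.09, −.02, 0]): positive in late
  winter–spring of year t−1, negative from autumn t−1 into winter of year
  t.  The "strong winter effect" ranking scenario concentrates a larger
  single negative lobe (γ = [0,0,0,0,−.12,−.15,−.03,0]) on the winter
  windows.

What a green recovery test does **not** establish: the generator is
year-by-class aggregated (no individual heterogeneity, no mark–recapture
observation error), density is exogenous, climate anomalies are independent
across windows (no autocorrelated weather regimes), and trial counts are
only order-of-magnitude realistic.  Conclusions about the real population
require the real data.

## Numerical choices

- Binomial log-likelihood computed from the linear predictor as
  `s·η − n·log(1+e^η)` (softplus via `logaddexp`), exact for extreme η
  where `p = logistic(η)` saturates in double precision; zero-trial cells
  contribute exactly 0 and keep year indexing rectangular.
- Missing weather days: linear interpolation on the date axis, edges
  extended with the nearest observed value; interpolation never leaves the
  range of the bracketing observations.
- Fortnight windows: fixed 14-day blocks anchored at 1 January of t−1; the
  42nd block is truncated at 31 July of t and averages only its available
  days, so leap years never change the window count.
- Centering refuses to run twice and refuses single-year matrices (all
  anomalies would be zero).
- Scalar covariates are standardized across study years before model entry,
  making their slope priors scale-free.
- elpd per year uses log-sum-exp; it cannot return −∞ unless every sampled
  likelihood underflows to exactly zero.
- Seeds: every public entry point takes one integer seed; sub-streams are
  spawned via `SeedSequence(seed, spawn_key=...)`, so stages are
  independently reproducible and bit-identical across runs.

## Known limitations

- `sigma_e` is weakly identified at 30 years: thresholded survival
  submodels carry no information about the axis in below-threshold years,
  so each year effect is measured against binomial noise of similar size to
  the residual sd itself.  The marginal posterior of `sigma_e` is
  right-skewed and its median systematically exceeds a small generating
  value (0.10) by 20-60% on a sizeable fraction of replicate datasets, even
  with long, well-mixed chains.  Point summaries of `sigma_e` from panels
  of this size should be read with the full interval, not the median alone.

- Random-walk Metropolis mixes slowly along the (β^e, σ_e) and fecundity
  (β⁰, β^e, β^f) ridges.  The desk profile recovers point summaries well
  (the recovery tests pass on it) but a substantial minority of parameters
  still flag at split-Rhat > 1.05 there; treat desk-profile interval
  estimates as provisional and re-run with longer chains (up to the paper
  profile) for final inference.  Short CV refits flag even more often; the
  flags are attached to every result and should be inspected.
- The threshold likelihood is only piecewise smooth in θ; sampling is
  correct but posterior θ intervals can be wide when few years sit above
  threshold.
- The cross-validated elpd is dominated by extreme (crash) years; on short
  panels single folds can swing model comparisons, which the per-year lpd
  table makes visible.
- No Pareto-smoothed importance sampling shortcut: every fold refits, as
  the marginal-elpd definition requires.
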