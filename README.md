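# semflm

Hierarchical Bayesian inference for age-structured vital rates driven by
shared latent environmental axes, with distributed-lag climate effects
entering through functional linear models (FLMs).

## The scientific problem

Wild populations show strong positive covariation in survival, reproduction
and twinning across age–sex classes: good years are good for everyone.  A
demographic structural equation model captures this with a single yearly
latent **environmental axis** `e(t)` shared by all vital-rate submodels,
decomposed into population density, a temporal trend, climate, and a
residual year effect:

```
e(t) = D_t − Σ_w f_c(w) C_tw − α_t · t − ε_t^e
```

where `D_t` is the log10 August population count, `C_tw` are seasonal
anomalies of a weather variable in lag window `w` (42 fortnights spanning
January of year t−1 through July of year t), and `f_c(w)` is a smooth lag
coefficient function — a natural cubic regression spline with 8 knots —
that lets the climate effect change magnitude and sign over the 19-month
window instead of forcing a single a-priori "critical window".

Eleven binomial submodels consume the axis.  Survival of five age–sex
classes is **thresholded** — flat below a density threshold θ, declining
above it:

```
logit S_t = β⁰ + β^t·t                      if e(t) < θ
logit S_t = β⁰ + β^t·t − β^e·(e(t) − θ)     if e(t) ≥ θ
```

while ram-lamb survival, reproduction and twinning respond linearly,
`logit R_t = β⁰ + β^t·t − β^e·e(t) (+ β^f·ε_t^f)`.  A second latent axis
`ε_t^f` loads on the three fecundity submodels the single-axis model
underfits; `(ε^e, ε^f)` are bivariate normal with sd(ε^f) ≡ 1.

Model variants (baseline one/two-axis, scalar climate covariate such as
winter NAO or March precipitation, FLM climate) are compared by
leave-one-**year**-out cross-validation with the *marginal* expected log
predictive density,

```
elpd = Σ_i log (1/SM) Σ_s Σ_m p(y_i | θ^{s,m}),
```

integrating the latent year effects out by Monte Carlo (`M` fresh draws per
posterior draw `s`), and reported on the deviance scale `−2(elpd_A −
elpd_B)`.

Because the 30-year field dataset that motivated this model is not publicly
deposited, the package ships a first-class synthetic-data generator with
fully known ground truth (density walk, daily weather with seasonal +
anomaly structure, latent axes, binomial panel), so parameter recovery,
lag-function recovery, model ranking and posterior-predictive calibration
are all testable end to end.

## Worked example

```python
import numpy as np
import semflm as sf
from semflm.basis import build_cr_basis
from semflm.mcmc import McmcConfig, run_mcmc

# a 30-year synthetic world with a two-lobe distributed-lag climate effect
scenario = sf.TruthScenario(seed=1,
                            params=sf.default_truth_params(with_climate=True))
data = sf.simulate_dataset(scenario)
panel, matrix = data["panel"], data["matrix"]

basis = build_cr_basis(matrix.n_windows, 8)
term = sf.FlmClimateTerm("climate", matrix.years, matrix.values, basis.basis)
spec = sf.ModelSpec("flm_climate", panel.submodels, climate_terms=[term],
                    priors=sf.PriorConfig.default_for(panel.density))
post = run_mcmc(panel, spec,
                McmcConfig(n_chains=2, n_burnin=15_000, n_iter=50_000,
                           thin=25, seed=1))

r2 = sf.bayes_r2(post, panel, spec)
print(f"axis R2: {r2['median']:.3f} ({r2['q2.5']:.3f}-{r2['q97.5']:.3f})")
fc_hat = basis.basis @ np.median(post.block("gamma_climate["), axis=0)
```

Output (about a minute on one CPU):

```
axis R2: 0.884 (0.731-0.948)
```

meaning 88% (95% interval 73–95%) of the year-to-year variance in the first
environmental axis is explained by its fixed effects (density, trend,
climate) rather than the residual year effect.  `fc_hat` is the posterior
median lag-coefficient function over the 42 fortnights; on this dataset it
correlates with the generating truth at r = 0.96, recovering the positive
late-winter/spring lobe in year t−1 and the negative autumn–winter lobe
going into year t.

The same pipeline is scriptable from the shell:

```sh
semflm simulate --seed 1 --outdir runs/sim --with-climate
semflm fit      --data-dir runs/sim --outdir runs/fit --variant flm_climate --seed 1
semflm cv       --data-dir runs/sim --outdir runs/cv \
                --variants baseline_2axis --variants flm_climate --seed 1
semflm report   --data-dir runs/sim --posterior runs/fit/posterior.csv \
                --outdir runs/report --variant flm_climate
```

`cv` writes per-year marginal elpd values and the deviance-scale comparison
table; `report` writes plot-ready tables (fitted rate-vs-axis curves,
observed-vs-predicted points, the posterior `f_c(w)` curve with draw
overlays).

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: it
simulates the default 30-year scenario with the known climate truth, fits
the FLM variant by MCMC, and recomputes the axis R², posterior-predictive
calibration, observed-vs-predicted correlations and lag-function recovery,
writing its results manifest to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `semflm.synthetic` — ground-truth scenario and generators
- `semflm.climate` — gap interpolation, fortnight/month window aggregation,
  seasonal centering, scalar covariates (winter NAO, March precipitation)
- `semflm.basis` — value-parameterized natural cubic ("cr") spline basis
- `semflm.model` — parameter space, priors, linear predictors, log posterior
- `semflm.mcmc` — in-house adaptive Metropolis-within-Gibbs, batched over
  chains and datasets; convergence diagnostics
- `semflm.evaluate` — LOYO marginal elpd, model comparison, Bayesian R²,
  posterior predictive checks, second-axis covariate screening
- `semflm.cli` / `semflm.io` — shell pipeline and CSV/YAML round-trips

See `docs/methods.md` for the modelling and numerical choices.
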