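"""Model evaluation: cluster cross-validation, R-squared, predictive checks.

Out-of-sample predictive performance is measured by leave-one-year-out
cluster cross-validation: the model is refitted once per study year with that
year's demographic outcomes withheld (its density and climate covariates stay
available as known covariates), and the held-out year's marginal expected log
predictive density is estimated by Monte Carlo,

    elpd_hat = sum_i log( (1/SM) sum_s sum_m p(y_i | theta_{s,m}) ),

with S posterior draws, M fresh draws of the latent year-effect pair
(eps_e, eps_f) from their fitted bivariate normal per posterior draw, and
p(y_i | .) the product of the 11 submodel binomial likelihoods.  Integrating
the year effects out by Monte Carlo avoids the optimism of conditioning on
fitted random effects.  Model pairs are compared on the deviance scale,
-2(elpd_A - elpd_B).

Also here: per-draw Bayesian R-squared of the first axis (share of its
variance explained by the fixed effects), posterior predictive tail checks
per cell, observed-vs-predicted correlations, and covariate screening for
the second axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from . import model as m
from .mcmc import McmcConfig, Posterior, run_mcmc, run_mcmc_batch

__all__ = [
    "ElpdResult",
    "PpcResult",
    "loyo_elpd",
    "held_out_lpd",
    "compare_models",
    "bayes_r2",
    "posterior_predictive_check",
    "obs_vs_pred",
    "axis_covariate_screen",
]


# ---------------------------------------------------------------------------
# Marginal elpd by leave-one-year-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ElpdResult:
    """Per-year marginal log predictive densities and their sum."""

    years: np.ndarray
    per_year_lpd: np.ndarray
    S: int                      # posterior draws per year
    M: int                      # random-effect draws per posterior draw
    mc_se: float
    per_year_se: np.ndarray
    flagged_years: list = field(default_factory=list)

    @property
    def elpd_hat(self) -> float:
        return float(self.per_year_lpd.sum())


def _split_rhat(arr: np.ndarray) -> np.ndarray:
    """Vectorized split-Rhat for (chains, draws, params); NaN where degenerate."""
    C, R, P = arr.shape
    half = R // 2
    if half < 2:
        return np.full(P, np.nan)
    splits = np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)
    means = splits.mean(axis=1)
    within = splits.var(axis=1, ddof=1).mean(axis=0)
    between = half * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (half - 1) / half * within + between / half
        return np.sqrt(var_hat / within)


def _extract_arrays(post: Posterior, spec: m.ModelSpec, idx: np.ndarray) -> dict:
    """Column blocks of the posterior needed for prediction, subset to idx."""
    sm = spec.submodels
    out = {
        "beta0": post.block("beta0[")[idx],
        "beta_t": post.block("beta_t[")[idx],
        "beta_e": post.block("beta_e[")[idx],
        "theta": post.block("theta[")[idx],
        "alpha_t": post.get("alpha_t")[idx],
        "sigma_e": post.get("sigma_e")[idx],
    }
    if spec.two_axis:
        out["beta_f"] = post.block("beta_f[")[idx]
        out["rho_ef"] = post.get("rho_ef")[idx]
    else:
        out["beta_f"] = np.zeros((len(idx), 0))
        out["rho_ef"] = np.zeros(len(idx))
    out["gamma"] = {t.name: post.block(f"gamma_{t.name}[")[idx]
                    for t in spec.climate_terms}
    return out


def held_out_lpd(post: Posterior, spec: m.ModelSpec, panel: m.DemographicPanel,
                 year: int, M: int, rng: np.random.Generator,
                 S: Optional[int] = None, chunk: int = 512
                 ) -> tuple[float, float]:
    """Marginal log predictive density of one held-out year.

    ``post`` is the posterior fitted without that year; the held-out year's
    density and climate covariates come from ``panel``.  The temporal
    covariate uses the training panel's centering.  Returns (lpd, mc_se),
    the Monte-Carlo standard error from the delta method on the sampled
    likelihood values.
    """
    sm = spec.submodels
    i = int(np.where(panel.years == year)[0][0])
    D_i = panel.density[i]
    t_i = year - float(post.years.mean())   # training-panel centering
    trials = panel.trials[:, i].astype(float)
    succ = panel.successes[:, i].astype(float)
    logC = float(m.binomial_log_coef(panel.trials[:, i], panel.successes[:, i]).sum())

    n_total = post.n_draws
    if S is None or S >= n_total:
        idx = np.arange(n_total)
    else:
        idx = np.unique(np.linspace(0, n_total - 1, S).round().astype(int))
    S_eff = len(idx)
    arr = _extract_arrays(post, spec, idx)

    clim_i = np.zeros(S_eff)
    for term in spec.climate_terms:
        design = term.design_for(np.array([year]))[0]          # (k,)
        clim_i += arr["gamma"][term.name] @ design

    is_thr = np.zeros(sm.n, dtype=bool)
    is_thr[sm.thresholded_idx] = True
    theta_full = np.zeros((S_eff, sm.n))
    if sm.n_thresholded:
        theta_full[:, sm.thresholded_idx] = arr["theta"]
    bf_full = np.zeros((S_eff, sm.n))
    if spec.two_axis and sm.n_second_axis:
        bf_full[:, sm.second_axis_idx] = arr["beta_f"]

    frozen_eps = "year_effects" in spec.frozen
    base_eta = arr["beta0"] + arr["beta_t"] * t_i              # (S, n)
    fixed_e = D_i - clim_i - arr["alpha_t"] * t_i              # (S,)

    ll = np.empty(S_eff * M)
    pos = 0
    for lo in range(0, S_eff, chunk):
        hi = min(lo + chunk, S_eff)
        cs = hi - lo
        if frozen_eps:
            eps_e = np.zeros((cs, M))
            eps_f = np.zeros((cs, M))
        else:
            z = rng.standard_normal((cs, M, 2))
            s_ = arr["sigma_e"][lo:hi, None]
            r_ = arr["rho_ef"][lo:hi, None]
            eps_e = s_ * z[:, :, 0]
            eps_f = r_ * z[:, :, 0] + np.sqrt(1.0 - r_ * r_) * z[:, :, 1]
        e = fixed_e[lo:hi, None] - eps_e                       # (cs, M)
        excess = np.maximum(e[:, :, None] - theta_full[lo:hi, None, :], 0.0)
        eff = np.where(is_thr[None, None, :], excess, e[:, :, None])
        eta = (base_eta[lo:hi, None, :] - arr["beta_e"][lo:hi, None, :] * eff
               + bf_full[lo:hi, None, :] * eps_f[:, :, None])  # (cs, M, n)
        cell = succ[None, None, :] * eta - trials[None, None, :] * np.logaddexp(0.0, eta)
        block = cell.sum(axis=2).ravel() + logC
        ll[pos:pos + cs * M] = block
        pos += cs * M

    shift = ll.max()
    w = np.exp(ll - shift)
    mean_w = w.mean()
    lpd = float(shift + math.log(mean_w) - 0.0)  # log of the average likelihood
    # delta method: se(log mean w) ~= sd(w) / (mean(w) * sqrt(SM))
    se = float(w.std(ddof=1) / (mean_w * math.sqrt(len(ll)))) if len(ll) > 1 else math.inf
    return lpd, se


def loyo_elpd(panel: m.DemographicPanel, spec: m.ModelSpec, config: McmcConfig,
              M: int = 1000, seed: int = 0, S: Optional[int] = None,
              rhat_flag: float = 1.05) -> ElpdResult:
    """Leave-one-year-out marginal elpd: refit once per held-out year.

    Years whose refit shows convergence trouble (split-Rhat above
    ``rhat_flag`` or sampler warnings) are listed in ``flagged_years`` --
    included in the sum, never silently dropped.
    """
    if panel.n_years < 3:
        raise ValueError("cross-validation needs at least 3 years")
    if M < 1:
        raise ValueError("M must be >= 1")
    folds = [panel.drop_year(int(y)) for y in panel.years]
    fit_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(0,))
                   .generate_state(1)[0] % (2 ** 31))
    posts = run_mcmc_batch(folds, [spec] * len(folds),
                           replace(config, seed=fit_seed))
    lpds = np.empty(panel.n_years)
    ses = np.empty(panel.n_years)
    flagged: list[int] = []
    for i, (year, post) in enumerate(zip(panel.years, posts)):
        bad = bool(post.warnings)
        if post.n_chains >= 2:
            R = post.n_draws // post.n_chains
            arr = post.draws.reshape(post.n_chains, R, -1)
            rh = _split_rhat(arr)
            finite = rh[np.isfinite(rh)]
            if finite.size and finite.max() > rhat_flag:
                bad = True
        if bad:
            flagged.append(int(year))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(int(year), 1)))
        lpds[i], ses[i] = held_out_lpd(post, spec, panel, int(year), M, rng, S=S)
    S_used = posts[0].n_draws if S is None else min(S, posts[0].n_draws)
    mc_se = float(np.sqrt((ses ** 2).sum()))
    return ElpdResult(panel.years.copy(), lpds, S_used, M, mc_se, ses, flagged)


def loyo_elpd_batch(panels: list, specs: list, config: McmcConfig,
                    M: int = 1000, seed: int = 0, S: Optional[int] = None,
                    rhat_flag: float = 1.05) -> list[ElpdResult]:
    """Leave-one-year-out elpd for several panel/spec pairs in one kernel call.

    All panels must share the year count and all specs the model structure;
    every fold of every panel becomes one item of a single batched MCMC run.
    Used for replicate experiments where refitting panels one by one would
    dominate the runtime.
    """
    if len(panels) != len(specs) or not panels:
        raise ValueError("need one spec per panel")
    folds, fold_specs = [], []
    for panel, spec in zip(panels, specs):
        if panel.n_years < 3:
            raise ValueError("cross-validation needs at least 3 years")
        for y in panel.years:
            folds.append(panel.drop_year(int(y)))
            fold_specs.append(spec)
    fit_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(0,))
                   .generate_state(1)[0] % (2 ** 31))
    posts = run_mcmc_batch(folds, fold_specs, replace(config, seed=fit_seed))
    results = []
    k = 0
    for pi, (panel, spec) in enumerate(zip(panels, specs)):
        lpds = np.empty(panel.n_years)
        ses = np.empty(panel.n_years)
        flagged: list[int] = []
        for i, year in enumerate(panel.years):
            post = posts[k]
            k += 1
            bad = bool(post.warnings)
            if post.n_chains >= 2:
                R = post.n_draws // post.n_chains
                rh = _split_rhat(post.draws.reshape(post.n_chains, R, -1))
                finite = rh[np.isfinite(rh)]
                if finite.size and finite.max() > rhat_flag:
                    bad = True
            if bad:
                flagged.append(int(year))
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(pi, int(year), 1)))
            lpds[i], ses[i] = held_out_lpd(post, spec, panel, int(year), M, rng, S=S)
        S_used = posts[0].n_draws if S is None else min(S, posts[0].n_draws)
        results.append(ElpdResult(panel.years.copy(), lpds, S_used, M,
                                  float(np.sqrt((ses ** 2).sum())), ses, flagged))
    return results


def compare_models(a: ElpdResult, b: ElpdResult) -> float:
    """Deviance-scale difference -2(elpd_A - elpd_B); negative favours A."""
    if len(a.years) != len(b.years) or np.any(a.years != b.years):
        raise ValueError("elpd results were computed on different year sets")
    return -2.0 * (a.elpd_hat - b.elpd_hat)


# ---------------------------------------------------------------------------
# Bayesian R-squared of the first axis
# ---------------------------------------------------------------------------

def bayes_r2(post: Posterior, panel: m.DemographicPanel, spec: m.ModelSpec
             ) -> dict[str, float]:
    """Share of first-axis variance explained by the fixed effects, per draw.

    R2 = Var_years(D_t - climate - alpha_t t) / (same + sigma_e^2); reported
    as the posterior median with 2.5/97.5% quantiles.
    """
    t = panel.t_centered
    idx = np.arange(post.n_draws)
    arr = _extract_arrays(post, spec, idx)
    clim = np.zeros((post.n_draws, panel.n_years))
    for term in spec.climate_terms:
        design = term.design_for(panel.years)                   # (T, k)
        clim += arr["gamma"][term.name] @ design.T
    fixed = panel.density[None, :] - clim - arr["alpha_t"][:, None] * t[None, :]
    vf = fixed.var(axis=1, ddof=1)
    if np.max(vf) == 0.0:
        raise ValueError("fixed part of the axis has zero variance across years; "
                         "R-squared undefined")
    r2 = vf / (vf + arr["sigma_e"] ** 2)
    lo, med, hi = np.quantile(r2, [0.025, 0.5, 0.975])
    return {"median": float(med), "q2.5": float(lo), "q97.5": float(hi)}


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

@dataclass
class PpcResult:
    """Per-cell predictive tail probabilities and flag summaries."""

    years: np.ndarray
    submodel_labels: list
    tail_prob: np.ndarray        # (n_submodels, T); NaN for zero-trial cells
    n_rep: int

    @property
    def flagged(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.tail_prob < 0.025) | (self.tail_prob > 0.975)

    @property
    def share_flagged(self) -> float:
        usable = ~np.isnan(self.tail_prob)
        return float(self.flagged[usable].mean())

    def share_flagged_by_submodel(self) -> np.ndarray:
        out = np.full(len(self.submodel_labels), np.nan)
        for j in range(len(self.submodel_labels)):
            usable = ~np.isnan(self.tail_prob[j])
            if usable.any():
                out[j] = self.flagged[j, usable].mean()
        return out


def posterior_predictive_check(post: Posterior, panel: m.DemographicPanel,
                               spec: m.ModelSpec, n_rep: int = 500,
                               seed: int = 0) -> PpcResult:
    """Simulate replicate panels from retained draws; per-cell tail checks.

    The tail probability is Pr(replicate >= observed) estimated over
    ``n_rep`` draws (subsampled evenly from the posterior, each with its own
    fitted year effects).  Zero-trial cells are reported as NaN.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    idx = np.unique(np.linspace(0, post.n_draws - 1, min(n_rep, post.n_draws))
                    .round().astype(int))
    ge_count = np.zeros(panel.trials.shape)
    for i in idx:
        params = post.unpack(int(i))
        p = m.success_probabilities(panel, params, spec)
        rep = rng.binomial(panel.trials, p)
        ge_count += rep >= panel.successes
    tail = ge_count / len(idx)
    tail[panel.trials == 0] = np.nan
    return PpcResult(panel.years.copy(), panel.submodels.labels, tail, len(idx))


# ---------------------------------------------------------------------------
# Observed vs predicted and covariate screening
# ---------------------------------------------------------------------------

def obs_vs_pred(post: Posterior, panel: m.DemographicPanel, spec: m.ModelSpec):
    """Pearson correlation of observed and predicted yearly proportions.

    Predictions use coordinate-wise posterior medians including the per-year
    year effects.  Submodels with fewer than 3 usable years or constant
    predictions get NaN.
    """
    import pandas as pd

    params = post.median_params()
    pred = m.success_probabilities(panel, params, spec)
    rows = []
    for j, label in enumerate(panel.submodels.labels):
        use = panel.trials[j] > 0
        n_use = int(use.sum())
        if n_use < 3:
            rows.append((label, np.nan, n_use))
            continue
        obs = panel.successes[j, use] / panel.trials[j, use]
        prd = pred[j, use]
        if np.std(prd) == 0 or np.std(obs) == 0:
            rows.append((label, np.nan, n_use))
            continue
        r = float(np.corrcoef(obs, prd)[0, 1])
        rows.append((label, r, n_use))
    return pd.DataFrame(rows, columns=["submodel", "pearson_r", "n_years"])


def axis_covariate_screen(post: Posterior, covariates: dict):
    """Posterior correlations between the second axis eps_f and covariates.

    For each retained draw, the Pearson correlation between the draw's
    eps_f_t series and each covariate; reported as posterior median with a
    95% interval.  Constant covariates yield NaN (undefined correlation).
    """
    import pandas as pd

    eps_f = post.block("eps_f[")
    if eps_f.shape[1] == 0:
        raise ValueError("posterior has no second-axis year effects")
    T = eps_f.shape[1]
    xc = eps_f - eps_f.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc ** 2).sum(axis=1))
    rows = []
    for name, cov in covariates.items():
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (T,):
            raise ValueError(f"covariate {name!r} length {cov.shape} != {T} years")
        cc = cov - cov.mean()
        cn = np.sqrt((cc ** 2).sum())
        if cn == 0:
            rows.append((name, np.nan, np.nan, np.nan))
            continue
        with np.errstate(invalid="ignore"):
            r = (xc @ cc) / (xn * cn)
        lo, med, hi = np.nanquantile(r, [0.025, 0.5, 0.975])
        rows.append((name, float(med), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["covariate", "median", "q2.5", "q97.5"])
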