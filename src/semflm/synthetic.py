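"""Synthetic demographic panels, density, climate and latent axes.

Stands in for the (undeposited) 30-year Soay sheep field dataset: generates
data with exactly the structure the SEM-FLM analysis assumes, from fully
known ground-truth parameters, so parameter recovery and model ranking are
testable end to end.

What the generator emulates, and how:

* **Density** -- an exogenous mean-reverting AR(1) walk on the log10 scale
  (the inferential model conditions on density, so no survival feedback).
* **Daily climate** -- seasonal sinusoid + a shared anomaly per 14-day block
  (constant within block, independent across blocks, sd ``yearly_anomaly_sd``)
  + iid daily noise, with a fraction of days set missing at random.  Because
  the anomalies are block-constant, aggregating to fortnight windows yields
  year-varying window anomalies for the FLM to recover.
* **Latent axes** -- (eps_e, eps_f) pairs drawn from the bivariate normal
  with sd(eps_f) = 1, then e(t) assembled by the active model variant's
  formula (the FLM truth is evaluated on the *aggregated, centered* climate
  matrix, so the truth effect is exactly expressible in the fitted model).
* **Panel** -- binomial draws from the model's own success probabilities;
  survival trial counts come from N_t times fixed class fractions,
  reproduction trials from the surviving female count of the class, twinning
  trials from the number of successful reproducers (giving realistic
  small-count behaviour in yearling twinning).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import model as m
from .basis import build_cr_basis, eval_flm
from .climate import ClimateMatrix, DailyClimateSeries, N_FORTNIGHTS

__all__ = [
    "ClimateScenario",
    "TruthScenario",
    "DensitySeries",
    "AxisState",
    "default_truth_params",
    "default_flm_gamma",
    "simulate_density",
    "simulate_climate_daily",
    "simulate_axes",
    "simulate_panel",
    "simulate_dataset",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible sub-stream for each simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# Scenario definitions
# ---------------------------------------------------------------------------

@dataclass
class ClimateScenario:
    """Generator settings for the daily weather series.

    seasonal_amplitude: within-year sinusoid amplitude (same units as the
    variable); yearly_anomaly_sd: sd of the shared per-14-day-block shift,
    the interannual signal the FLM acts on; daily_noise_sd: iid daily noise;
    missing_fraction: share of days masked at random (< 0.5).
    """

    seasonal_amplitude: float = 6.0
    daily_noise_sd: float = 2.0
    yearly_anomaly_sd: float = 0.6
    missing_fraction: float = 0.02

    def __post_init__(self) -> None:
        if min(self.seasonal_amplitude, self.daily_noise_sd, self.yearly_anomaly_sd) < 0:
            raise ValueError("amplitude and sd parameters must be >= 0")
        if not (0 <= self.missing_fraction < 0.5):
            raise ValueError("missing_fraction must lie in [0, 0.5)")


def default_flm_gamma() -> np.ndarray:
    """Ground-truth spline coefficients for the lag function f_c(w).

    Two smooth lobes over the 42 fortnights: positive in late winter-spring
    of year t-1 (around windows 5-15) and negative over autumn t-1 into
    winter of year t (around windows 20-34), mirroring the qualitative shape
    of the fitted wind-speed lag function.  Knots are the default 8, evenly
    spaced over [1, 42].
    """
    return np.array([0.0, 0.05, 0.08, 0.0, -0.07, -0.09, -0.02, 0.0])


def default_truth_params(n_flm_knots: int = 8,
                         flm_gamma: Optional[np.ndarray] = None,
                         with_climate: bool = False) -> m.Parameters:
    """Ground truth for the standard 11-submodel two-axis model.

    Magnitudes sit on the observed Soay scales: survival intercepts give
    below-threshold survival of roughly 0.8-0.93, axis loadings of 6-9 on the
    thresholded submodels reproduce crash-year survival collapses over a
    ~0.2-unit density range, and non-thresholded intercepts absorb
    beta_e * mean(e) on the uncentered log10-density axis.  No submodel-level
    temporal trends (beta_t = 0); the trend lives in the axis (alpha_t).
    """
    params = m.Parameters(
        beta0=np.array([1.4, 6.8, 2.2, 2.0, 2.6, 2.2, 5.9, 6.0, 5.9, -0.2, 2.4]),
        beta_t=np.zeros(11),
        beta_e=np.array([9.0, 2.0, 7.0, 8.0, 6.0, 8.0, 2.5, 2.0, 1.5, 1.0, 1.5]),
        theta=np.array([2.80, 2.78, 2.80, 2.82, 2.84]),
        beta_f=np.array([0.8, 0.5, 0.5]),
        alpha_t=0.02,
        sigma_e=0.10,
        rho_ef=0.3,
    )
    if with_climate:
        gamma = default_flm_gamma() if flm_gamma is None else np.asarray(flm_gamma, float)
        if len(gamma) != n_flm_knots:
            raise ValueError("flm_gamma length must equal n_flm_knots")
        params.climate = {"climate": gamma}
    return params


@dataclass
class TruthScenario:
    """A fully specified synthetic world."""

    n_years: int = 30
    start_year: int = 1985
    submodel_spec: m.SubmodelSpec = field(default_factory=m.SubmodelSpec.standard)
    params: m.Parameters = field(default_factory=default_truth_params)
    density_mean_log10: float = 2.78
    density_sd_log10: float = 0.12
    density_ar1: float = 0.6
    class_fractions: np.ndarray = field(
        default_factory=lambda: np.full(6, 1.0 / 6.0))
    climate: ClimateScenario = field(default_factory=ClimateScenario)
    n_flm_knots: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_fractions = np.asarray(self.class_fractions, dtype=float)
        if self.n_years < 3:
            raise ValueError("need n_years >= 3")
        if self.density_sd_log10 < 0:
            raise ValueError("density_sd_log10 must be >= 0")
        if np.any(self.class_fractions <= 0) or np.any(self.class_fractions >= 1):
            raise ValueError("class fractions must lie in (0, 1)")
        if self.class_fractions.sum() > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        if not (0 <= self.density_ar1 < 1):
            raise ValueError("density_ar1 must lie in [0, 1)")
        # sigma_e == 0 is allowed in the generator (degenerate no-residual
        # world); the inferential model itself requires sigma_e > 0
        if self.params.sigma_e < 0 or abs(self.params.rho_ef) >= 1:
            raise ValueError("truth params fail covariance invariants")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)

    @property
    def has_flm_truth(self) -> bool:
        return any(np.atleast_1d(v).size > 1 for v in self.params.climate.values())


@dataclass
class DensitySeries:
    years: np.ndarray
    log10_count: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.log10_count = np.asarray(self.log10_count, dtype=float)
        self.count = np.asarray(self.count, dtype=int)


@dataclass
class AxisState:
    """Yearly first-axis values and the latent year-effect pairs."""

    years: np.ndarray
    e: np.ndarray
    eps_e: np.ndarray
    eps_f: np.ndarray
    sigma: np.ndarray  # 2x2 covariance of (eps_e, eps_f)


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_density(scenario: TruthScenario) -> DensitySeries:
    """Mean-reverting AR(1) series of log10 August counts.

    Stationary mean/sd equal the scenario's density_mean_log10/sd; rejects
    parameterizations that produce populations below 30 animals (trial
    counts would degenerate).
    """
    rng = _rng(scenario.seed, 0)
    mu, sd, phi = (scenario.density_mean_log10, scenario.density_sd_log10,
                   scenario.density_ar1)
    D = np.empty(scenario.n_years)
    D[0] = mu + sd * rng.standard_normal()
    innov_sd = sd * np.sqrt(1 - phi * phi)
    for t in range(1, scenario.n_years):
        D[t] = mu + phi * (D[t - 1] - mu) + innov_sd * rng.standard_normal()
    counts = np.round(10.0 ** D).astype(int)
    if np.any(counts < 30):
        raise ValueError("density scenario produced a population below 30; "
                         "raise density_mean_log10 or lower density_sd_log10")
    return DensitySeries(scenario.years, D, counts)


def simulate_climate_daily(scenario: TruthScenario,
                           variable_name: str = "climate") -> DailyClimateSeries:
    """Daily series spanning 1 Jan of (first study year - 1) .. 31 Jul of the last.

    value = seasonal sinusoid + per-14-day-block anomaly + daily noise, with
    a ``missing_fraction`` share of days masked at random.
    """
    cs = scenario.climate
    rng = _rng(scenario.seed, 1)
    start = pd.Timestamp(scenario.start_year - 1, 1, 1)
    end = pd.Timestamp(scenario.start_year + scenario.n_years - 1, 7, 31)
    dates = pd.date_range(start, end, freq="D")
    ndays = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = cs.seasonal_amplitude * np.cos(2 * np.pi * (doy - 196) / 365.25)
    block = np.arange(ndays) // 14
    anomalies = cs.yearly_anomaly_sd * rng.standard_normal(block[-1] + 1)
    values = seasonal + anomalies[block] + cs.daily_noise_sd * rng.standard_normal(ndays)
    if cs.missing_fraction > 0:
        mask = rng.random(ndays) < cs.missing_fraction
        values = np.where(mask, np.nan, values)
    return DailyClimateSeries(dates, values, variable_name)


def _truth_climate_contribution(scenario: TruthScenario, climate) -> np.ndarray:
    """Per-year climate contribution implied by the truth parameters."""
    T = scenario.n_years
    if climate is None or not scenario.params.climate:
        return np.zeros(T)
    (name, coef), = scenario.params.climate.items()
    coef = np.atleast_1d(np.asarray(coef, dtype=float))
    if isinstance(climate, ClimateMatrix):
        if coef.size == 1:
            raise ValueError("scalar climate truth needs a per-year covariate, "
                             "not a lag-window matrix")
        term = build_cr_basis(climate.n_windows, len(coef), variable_name=name)
        fc = eval_flm(term.with_gamma(coef))
        rows = np.searchsorted(climate.years, scenario.years)
        return climate.values[rows] @ fc
    cov = np.asarray(climate, dtype=float)
    if coef.size != 1 or cov.shape != (T,):
        raise ValueError("per-year covariate truth needs a length-1 slope and "
                         "a length-n_years series")
    return float(coef[0]) * cov


def simulate_axes(scenario: TruthScenario, density: DensitySeries,
                  climate=None) -> AxisState:
    """Draw latent year-effect pairs and assemble the first axis e(t).

    ``climate`` is either None (baseline truth), a centered
    :class:`~semflm.climate.ClimateMatrix` (FLM truth) or a per-year array
    (scalar-covariate truth).
    """
    if len(density.years) != scenario.n_years:
        raise ValueError("density length must equal scenario n_years")
    p = scenario.params
    s, r = p.sigma_e, p.rho_ef
    sigma = np.array([[s * s, r * s], [r * s, 1.0]])
    if s < 0 or abs(r) >= 1:
        raise ValueError("year-effect covariance is not positive definite")
    rng = _rng(scenario.seed, 2)
    z = rng.standard_normal((scenario.n_years, 2))
    if s == 0.0:
        # degenerate first axis: eps_e identically zero, eps_f standard normal
        eps_e, eps_f = np.zeros(scenario.n_years), z[:, 1]
    else:
        chol = np.linalg.cholesky(sigma)
        eps = z @ chol.T
        eps_e, eps_f = eps[:, 0], eps[:, 1]
    t = scenario.years - scenario.years.mean()
    contrib = _truth_climate_contribution(scenario, climate)
    e = density.log10_count - contrib - p.alpha_t * t - eps_e
    return AxisState(scenario.years, e, eps_e, eps_f, sigma)


def _class_trial_index(spec: m.SubmodelSpec) -> dict[int, int]:
    """Map survival submodel id -> position in class_fractions.

    Order: lamb F, lamb M, yearling F, yearling M, adult F, adult M.
    """
    order = [("lamb", "F"), ("lamb", "M"), ("yearling", "F"),
             ("yearling", "M"), ("adult", "F"), ("adult", "M")]
    out = {}
    for s in spec.submodels:
        if s.process == "survival":
            out[s.id] = order.index((s.age, s.sex))
    return out


def simulate_panel(scenario: TruthScenario, axes: AxisState,
                   density: DensitySeries) -> m.DemographicPanel:
    """Draw the binomial demographic panel from the truth parameters.

    Survival trials are ``round(N_t * class_fraction)``; reproduction trials
    are the surviving female count of the class; twinning trials are the
    count of successful reproducers.  Zero-trial cells are legal output.
    """
    if len(axes.years) != scenario.n_years or len(density.years) != scenario.n_years:
        raise ValueError("axes/density inconsistent with scenario length")
    spec_sm = scenario.submodel_spec
    variant = "flm_climate" if scenario.has_flm_truth else "baseline_2axis"
    # probabilities are computed from the realized axis directly, so the
    # climate decomposition of e(t) is irrelevant here
    mspec = m.ModelSpec("baseline_2axis", spec_sm,
                        priors=m.PriorConfig.default_for(density.log10_count))
    params = scenario.params.with_effects(axes.eps_e, axes.eps_f)
    T = scenario.n_years
    panel_stub = m.DemographicPanel(
        years=scenario.years, density=density.log10_count,
        trials=np.zeros((spec_sm.n, T), dtype=int),
        successes=np.zeros((spec_sm.n, T), dtype=int), submodels=spec_sm)
    from scipy.special import expit
    probs = expit(m.linpred_matrix(panel_stub, params, mspec, e=axes.e))

    rng = _rng(scenario.seed, 3)
    trials = np.zeros((spec_sm.n, T), dtype=int)
    successes = np.zeros((spec_sm.n, T), dtype=int)
    cls_idx = _class_trial_index(spec_sm)

    surv_successes: dict[tuple[str, str], np.ndarray] = {}
    for s in spec_sm.submodels:
        if s.process != "survival":
            continue
        n_tr = np.round(density.count * scenario.class_fractions[cls_idx[s.id]]).astype(int)
        trials[s.id] = n_tr
        successes[s.id] = rng.binomial(n_tr, probs[s.id])
        surv_successes[(s.age, s.sex)] = successes[s.id]

    repro_successes: dict[str, np.ndarray] = {}
    for s in spec_sm.submodels:
        if s.process != "reproduction":
            continue
        n_tr = surv_successes.get((s.age, "F"), np.zeros(T, dtype=int))
        trials[s.id] = n_tr
        successes[s.id] = rng.binomial(n_tr, probs[s.id])
        repro_successes[s.age] = successes[s.id]

    for s in spec_sm.submodels:
        if s.process != "twinning":
            continue
        n_tr = repro_successes.get(s.age, np.zeros(T, dtype=int))
        trials[s.id] = n_tr
        successes[s.id] = rng.binomial(n_tr, probs[s.id])

    return m.DemographicPanel(scenario.years, density.log10_count,
                              trials, successes, spec_sm)


def simulate_dataset(scenario: TruthScenario):
    """Full pipeline: density, daily climate, aggregated anomalies, axes, panel.

    Returns a dict with keys density, daily, matrix (centered ClimateMatrix or
    None), axes, panel.  The climate matrix is built through the package's own
    preprocessing (interpolation, fortnight aggregation, centering), so the
    generated panel is consistent with what a fit of the FLM variant consumes.
    """
    from .climate import aggregate_windows, center_windows, interpolate_missing

    density = simulate_density(scenario)
    daily = simulate_climate_daily(scenario)
    matrix = None
    climate_arg = None
    if scenario.has_flm_truth:
        filled = interpolate_missing(daily)
        matrix = center_windows(aggregate_windows(filled, scenario.years, "fortnight"))
        climate_arg = matrix
    axes = simulate_axes(scenario, density, climate_arg)
    panel = simulate_panel(scenario, axes, density)
    return {"density": density, "daily": daily, "matrix": matrix,
            "axes": axes, "panel": panel}
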