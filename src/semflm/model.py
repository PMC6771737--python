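"""Model definition: parameter space, priors, linear predictors, log posterior.

The demographic structural equation model treats eleven binomial vital-rate
submodels (survival of six age-sex classes, reproduction of ewes in three age
classes, twinning of yearling and adult ewes) as jointly driven by a latent
yearly environmental axis

    e(t) = D_t - (climate contribution) - alpha_t * t - eps_e_t,

where ``D_t`` is log10 August population count, ``t`` a centered year index
and ``eps_e_t`` a residual year effect.  Survival submodels (except ram
lambs) respond to the axis through a threshold: flat below ``theta`` and
declining above it.  A second latent axis ``eps_f_t`` loads on the three
fecundity submodels that the single-axis model underfits; the pair
``(eps_e, eps_f)`` is bivariate normal with sd(eps_f) fixed at 1 for
identifiability.  Climate enters the axis either as a scalar yearly covariate
(``beta_m * M_t``) or as a distributed-lag functional linear term
``sum_w f_c(w) C_tw`` with ``f_c`` a cubic regression spline (see
:mod:`semflm.basis`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Submodel",
    "SubmodelSpec",
    "standard_submodels",
    "Parameters",
    "PriorConfig",
    "DemographicPanel",
    "ScalarClimateTerm",
    "FlmClimateTerm",
    "ModelSpec",
    "VARIANTS",
    "axis_value",
    "axis_values",
    "climate_contribution",
    "linpred",
    "linpred_matrix",
    "success_probabilities",
    "log_likelihood",
    "log_prior",
    "log_prior_blocks",
    "log_posterior",
]

LOG_HALF_NORMAL_CONST = 0.5 * math.log(2.0) - 0.5 * math.log(math.pi)

VARIANTS = ("baseline_1axis", "baseline_2axis", "scalar_climate", "flm_climate")

# Block names that may be frozen (excluded from sampling, held at their
# initial values).  Used for degenerate test models (e.g. an intercept-only
# single-submodel model), never for the standard analysis.
FREEZABLE_BLOCKS = frozenset(
    {"beta_t", "beta_e", "theta", "beta_f", "axis", "year_effects", "variance"}
)


# ---------------------------------------------------------------------------
# Submodel structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Submodel:
    """One vital-rate submodel (a binomial process for an age-sex class)."""

    id: int
    process: str  # "survival" | "reproduction" | "twinning"
    age: str      # "lamb" | "yearling" | "adult"
    sex: str      # "F" | "M"
    thresholded: bool
    second_axis: bool

    @property
    def label(self) -> str:
        short = {"survival": "surv", "reproduction": "repro", "twinning": "twin"}
        return f"{short[self.process]}_{self.age}_{self.sex.lower()}"


def standard_submodels() -> list[Submodel]:
    """The eleven standard submodels.

    Thresholds apply to the five survival submodels excluding ram lambs; the
    second axis loads on lamb reproduction, adult reproduction and adult
    twinning.
    """
    rows = [
        # (process, age, sex, thresholded, second_axis)
        ("survival", "lamb", "F", True, False),
        ("survival", "lamb", "M", False, False),
        ("survival", "yearling", "F", True, False),
        ("survival", "yearling", "M", True, False),
        ("survival", "adult", "F", True, False),
        ("survival", "adult", "M", True, False),
        ("reproduction", "lamb", "F", False, True),
        ("reproduction", "yearling", "F", False, False),
        ("reproduction", "adult", "F", False, True),
        ("twinning", "yearling", "F", False, False),
        ("twinning", "adult", "F", False, True),
    ]
    return [Submodel(i, *r) for i, r in enumerate(rows)]


@dataclass
class SubmodelSpec:
    """Ordered collection of submodels with index helpers.

    ``validate_standard`` enforces the canonical structure (6 survival,
    3 reproduction, 2 twinning; thresholds on the five non-ram-lamb survival
    submodels; second axis on lamb/adult reproduction and adult twinning).
    Non-standard collections are permitted for reduced test models.
    """

    submodels: list[Submodel]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.submodels]
        if ids != list(range(len(self.submodels))):
            raise ValueError("submodel ids must be 0..n-1 in order")

    # -- index helpers ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.submodels)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.submodels]

    @property
    def thresholded_idx(self) -> np.ndarray:
        return np.array([s.id for s in self.submodels if s.thresholded], dtype=int)

    @property
    def second_axis_idx(self) -> np.ndarray:
        return np.array([s.id for s in self.submodels if s.second_axis], dtype=int)

    @property
    def n_thresholded(self) -> int:
        return len(self.thresholded_idx)

    @property
    def n_second_axis(self) -> int:
        return len(self.second_axis_idx)

    def theta_position(self, submodel_id: int) -> int:
        """Position of a submodel's threshold within the theta vector."""
        idx = self.thresholded_idx
        pos = np.where(idx == submodel_id)[0]
        if len(pos) == 0:
            raise ValueError(f"submodel {submodel_id} is not thresholded")
        return int(pos[0])

    @property
    def beta_f_positive_pos(self) -> Optional[int]:
        """Position (within beta_f) of the sign-constrained loading.

        The adult-reproduction loading is constrained positive to pin the sign
        of the second axis.
        """
        for pos, sid in enumerate(self.second_axis_idx):
            s = self.submodels[sid]
            if s.process == "reproduction" and s.age == "adult":
                return pos
        return None

    def validate_standard(self) -> None:
        counts = {"survival": 0, "reproduction": 0, "twinning": 0}
        for s in self.submodels:
            counts[s.process] += 1
        if counts != {"survival": 6, "reproduction": 3, "twinning": 2}:
            raise ValueError(f"expected 6/3/2 survival/reproduction/twinning, got {counts}")
        for s in self.submodels:
            expect_thr = s.process == "survival" and not (s.age == "lamb" and s.sex == "M")
            if s.thresholded != expect_thr:
                raise ValueError(f"threshold flag wrong for {s.label}")
            expect_f = (s.process, s.age) in {("reproduction", "lamb"),
                                              ("reproduction", "adult"),
                                              ("twinning", "adult")}
            if s.second_axis != expect_f:
                raise ValueError(f"second-axis flag wrong for {s.label}")

    @classmethod
    def standard(cls) -> "SubmodelSpec":
        spec = cls(standard_submodels())
        spec.validate_standard()
        return spec


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class DemographicPanel:
    """Per-year, per-submodel binomial trials and successes plus density."""

    years: np.ndarray           # (T,) integer study-year labels
    density: np.ndarray         # (T,) D_t = log10 August count
    trials: np.ndarray          # (n_submodels, T)
    successes: np.ndarray       # (n_submodels, T)
    submodels: SubmodelSpec

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.density = np.asarray(self.density, dtype=float)
        self.trials = np.asarray(self.trials, dtype=int)
        self.successes = np.asarray(self.successes, dtype=int)
        T = len(self.years)
        if self.density.shape != (T,):
            raise ValueError("density length must match years")
        if self.trials.shape != (self.submodels.n, T):
            raise ValueError("trials must be (n_submodels, n_years)")
        if self.successes.shape != self.trials.shape:
            raise ValueError("successes shape must match trials")
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise ValueError("need 0 <= successes <= trials elementwise")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def t_centered(self) -> np.ndarray:
        """Centered year index used as the temporal-trend covariate."""
        return self.years - self.years.mean()

    def drop_year(self, year: int) -> "DemographicPanel":
        keep = self.years != year
        if keep.all():
            raise ValueError(f"year {year} not in panel")
        return DemographicPanel(
            years=self.years[keep],
            density=self.density[keep],
            trials=self.trials[:, keep],
            successes=self.successes[:, keep],
            submodels=self.submodels,
        )


# ---------------------------------------------------------------------------
# Climate terms
# ---------------------------------------------------------------------------

def _align(years_have: np.ndarray, years_want: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(years_have, years_want)
    if np.any(idx >= len(years_have)) or np.any(years_have[np.clip(idx, 0, None)] != years_want):
        missing = sorted(set(years_want.tolist()) - set(years_have.tolist()))
        raise ValueError(f"climate term missing years {missing}")
    return idx


@dataclass
class ScalarClimateTerm:
    """A scalar yearly covariate M_t entering the axis as beta_m * M_t."""

    name: str
    years: np.ndarray
    values: np.ndarray  # (T,), standardized before model entry

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_coef(self) -> int:
        return 1

    def design_for(self, years: np.ndarray) -> np.ndarray:
        """(T, 1) design: contribution = design @ [beta_m]."""
        return self.values[_align(self.years, np.asarray(years))][:, None]


@dataclass
class FlmClimateTerm:
    """A year x lag-window anomaly matrix entering through a spline f_c(w)."""

    name: str
    years: np.ndarray
    matrix: np.ndarray        # (T, W) centered anomalies C_tw
    basis: np.ndarray         # (W, K) cr-spline basis B

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if self.matrix.shape[1] != self.basis.shape[0]:
            raise ValueError("window count of matrix and basis disagree")

    @property
    def n_coef(self) -> int:
        return self.basis.shape[1]

    def design_for(self, years: np.ndarray) -> np.ndarray:
        """(T, K) design: contribution = design @ gamma = C @ B @ gamma."""
        rows = _align(self.years, np.asarray(years))
        return self.matrix[rows] @ self.basis


ClimateTerm = Union[ScalarClimateTerm, FlmClimateTerm]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass
class PriorConfig:
    """Weakly informative default priors.

    The default scales are wide (10) and deliberately judged against the
    covariate scales of this model: the latent axis moves over a few tenths
    of a log10-density unit, so axis loadings of magnitude 5-10 are ordinary,
    and on the uncentered density scale the intercepts of non-thresholded
    submodels absorb ``beta_e * mean(e)`` and sit several units from zero.
    Tighter "unit-scale" priors measurably attenuate the loadings along the
    weakly identified (beta_e, sigma_e) ridge.  ``theta_bounds`` give the
    uniform prior support for each threshold, by default the central 90%
    range of the observed density series.  ``beta0_logit_uniform`` swaps the
    normal prior on the intercepts for the logistic-Jacobian density (uniform
    on the probability scale); used only in reduced conjugate test models.
    """

    beta0_sd: float = 10.0
    slope_sd: float = 10.0       # beta_t, beta_e, beta_f, alpha_t, beta_m, gamma
    sigma_e_scale: float = 1.0   # Half-Normal scale
    theta_bounds: tuple[float, float] = (0.0, 1.0)
    beta0_logit_uniform: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.theta_bounds
        if not (hi > lo):
            raise ValueError("theta_bounds must be an increasing pair")
        if min(self.beta0_sd, self.slope_sd, self.sigma_e_scale) <= 0:
            raise ValueError("prior scales must be positive")

    @classmethod
    def default_for(cls, density: np.ndarray, **kw) -> "PriorConfig":
        """Priors with theta support set to the central 90% density range."""
        lo, hi = np.quantile(np.asarray(density, dtype=float), [0.05, 0.95])
        if not hi > lo:
            # degenerate (constant density); widen artificially
            lo, hi = lo - 0.5, hi + 0.5
        return cls(theta_bounds=(float(lo), float(hi)), **kw)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class Parameters:
    """One point in the model's parameter space.

    ``climate`` maps each climate term's name to its coefficient vector
    (length 1 for a scalar covariate, n_knots for an FLM term).  ``eps_e`` and
    ``eps_f`` are the latent year effects; ``eps_f`` is all zero under
    single-axis variants.
    """

    beta0: np.ndarray                     # (n,)
    beta_t: np.ndarray                    # (n,)
    beta_e: np.ndarray                    # (n,)
    theta: np.ndarray                     # (n_thresholded,)
    beta_f: np.ndarray                    # (n_second_axis,)
    alpha_t: float
    sigma_e: float
    rho_ef: float = 0.0
    climate: dict = field(default_factory=dict)
    eps_e: Optional[np.ndarray] = None    # (T,)
    eps_f: Optional[np.ndarray] = None    # (T,)

    def __post_init__(self) -> None:
        for name in ("beta0", "beta_t", "beta_e", "theta", "beta_f"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        for name in ("eps_e", "eps_f"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    def validate(self, spec: "ModelSpec") -> None:
        sm = spec.submodels
        if self.beta0.shape != (sm.n,) or self.beta_t.shape != (sm.n,) or self.beta_e.shape != (sm.n,):
            raise ValueError("per-submodel parameter vectors must have length n_submodels")
        if self.theta.shape != (sm.n_thresholded,):
            raise ValueError("theta length must match the thresholded submodels")
        if spec.two_axis and self.beta_f.shape != (sm.n_second_axis,):
            raise ValueError("beta_f length must match second-axis submodels")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")
        if abs(self.rho_ef) >= 1:
            raise ValueError("|rho_ef| must be < 1")
        for term in spec.climate_terms:
            g = np.atleast_1d(np.asarray(self.climate.get(term.name)))
            if g.shape != (term.n_coef,):
                raise ValueError(f"climate coefficients for {term.name!r} must have length {term.n_coef}")

    def with_effects(self, eps_e: np.ndarray, eps_f: Optional[np.ndarray] = None) -> "Parameters":
        return replace(self, eps_e=np.asarray(eps_e, dtype=float),
                       eps_f=None if eps_f is None else np.asarray(eps_f, dtype=float))


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A model variant: submodel structure, climate terms and priors."""

    variant: str
    submodels: SubmodelSpec
    climate_terms: list = field(default_factory=list)
    priors: PriorConfig = field(default_factory=PriorConfig)
    frozen: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant.startswith("baseline") and self.climate_terms:
            raise ValueError("baseline variants carry no climate terms")
        if self.variant in ("scalar_climate", "flm_climate") and not self.climate_terms:
            raise ValueError(f"variant {self.variant!r} requires at least one climate term")
        unknown = set(self.frozen) - FREEZABLE_BLOCKS
        if unknown:
            raise ValueError(f"unknown frozen blocks {sorted(unknown)}")
        self.frozen = frozenset(self.frozen)

    @property
    def two_axis(self) -> bool:
        # The climate analysis runs on the two-axis model.
        return self.variant != "baseline_1axis"


# ---------------------------------------------------------------------------
# Linear predictors
# ---------------------------------------------------------------------------

def axis_value(D_t: float, t: float, alpha_t: float, climate_contrib: float,
               eps_e_t: float) -> float:
    """First environmental axis e(t) = D_t - climate - alpha_t * t - eps_e_t."""
    return D_t - climate_contrib - alpha_t * t - eps_e_t


def climate_contribution(params: Parameters, spec: ModelSpec,
                         years: np.ndarray) -> np.ndarray:
    """Summed per-year climate contribution across all terms; (T,)."""
    years = np.asarray(years)
    out = np.zeros(len(years))
    for term in spec.climate_terms:
        coef = np.atleast_1d(np.asarray(params.climate[term.name], dtype=float))
        out += term.design_for(years) @ coef
    return out


def axis_values(panel: DemographicPanel, params: Parameters, spec: ModelSpec) -> np.ndarray:
    """Vector of e(t) over the panel years."""
    eps = params.eps_e if params.eps_e is not None else np.zeros(panel.n_years)
    clim = climate_contribution(params, spec, panel.years)
    return panel.density - clim - params.alpha_t * panel.t_centered - eps


def linpred(submodel: Submodel, params: Parameters, e_t: float,
            eps_f_t: Optional[float], t: float, spec: ModelSpec) -> float:
    """Logit-scale linear predictor for one submodel in one year.

    Thresholded survival: eta = beta0 + beta_t*t for e < theta, and
    eta = beta0 + beta_t*t - beta_e*(e - theta) for e >= theta.
    Non-thresholded: eta = beta0 + beta_t*t - beta_e*e (+ beta_f*eps_f if the
    submodel loads on the second axis).
    """
    if eps_f_t is not None and not submodel.second_axis:
        raise ValueError(f"submodel {submodel.label} does not load on the second axis")
    i = submodel.id
    eta = params.beta0[i] + params.beta_t[i] * t
    if submodel.thresholded:
        th = params.theta[spec.submodels.theta_position(i)]
        if e_t >= th:
            eta -= params.beta_e[i] * (e_t - th)
    else:
        eta -= params.beta_e[i] * e_t
        if submodel.second_axis:
            if eps_f_t is None:
                raise ValueError(f"submodel {submodel.label} requires eps_f_t")
            pos = int(np.where(spec.submodels.second_axis_idx == i)[0][0])
            eta += params.beta_f[pos] * eps_f_t
    return float(eta)


def linpred_matrix(panel: DemographicPanel, params: Parameters, spec: ModelSpec,
                   e: Optional[np.ndarray] = None) -> np.ndarray:
    """(n_submodels, T) matrix of logit-scale linear predictors."""
    sm = spec.submodels
    t = panel.t_centered
    if e is None:
        e = axis_values(panel, params, spec)
    eta = params.beta0[:, None] + params.beta_t[:, None] * t[None, :]
    thr = sm.thresholded_idx
    nonthr = np.setdiff1d(np.arange(sm.n), thr)
    if len(thr):
        excess = np.maximum(e[None, :] - params.theta[:, None], 0.0)
        eta[thr] -= params.beta_e[thr, None] * excess
    if len(nonthr):
        eta[nonthr] -= params.beta_e[nonthr, None] * e[None, :]
    if spec.two_axis and sm.n_second_axis:
        eps_f = params.eps_f if params.eps_f is not None else np.zeros(panel.n_years)
        eta[sm.second_axis_idx] += params.beta_f[:, None] * eps_f[None, :]
    return eta


def success_probabilities(panel: DemographicPanel, params: Parameters,
                          spec: ModelSpec) -> np.ndarray:
    """(n_submodels, T) success probabilities via the logistic link."""
    from scipy.special import expit
    return expit(linpred_matrix(panel, params, spec))


# ---------------------------------------------------------------------------
# Likelihood, prior, posterior
# ---------------------------------------------------------------------------

def binomial_log_coef(trials: np.ndarray, successes: np.ndarray) -> np.ndarray:
    """log C(n, k) elementwise; zero for zero-trial cells."""
    n = np.asarray(trials, dtype=float)
    k = np.asarray(successes, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def loglik_cells(panel: DemographicPanel, params: Parameters, spec: ModelSpec,
                 eta: Optional[np.ndarray] = None) -> np.ndarray:
    """(n, T) per-cell binomial log-pmf, including the binomial coefficient."""
    if eta is None:
        eta = linpred_matrix(panel, params, spec)
    n = panel.trials
    s = panel.successes
    # s*eta - n*log(1+exp(eta)), stable via logaddexp
    return s * eta - n * np.logaddexp(0.0, eta) + binomial_log_coef(n, s)


def log_likelihood(panel: DemographicPanel, params: Parameters, spec: ModelSpec) -> float:
    """Binomial log likelihood summed over years and submodels.

    Zero-trial cells contribute exactly 0.
    """
    return float(loglik_cells(panel, params, spec).sum())


def _normal_logpdf(x: np.ndarray, sd: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def year_effect_logpdf(eps_e: np.ndarray, eps_f: Optional[np.ndarray],
                       sigma_e: float, rho_ef: float, two_axis: bool) -> float:
    """Log density of the latent year effects under their (MV) normal law."""
    if not two_axis or eps_f is None:
        return float(_normal_logpdf(eps_e, sigma_e).sum())
    # bivariate normal, sd(eps_f) = 1, correlation rho
    s, r = sigma_e, rho_ef
    det = s * s * (1 - r * r)
    z = (eps_f * eps_f - 2 * r * (eps_e / s) * eps_f + (eps_e / s) ** 2) / (1 - r * r)
    T = len(eps_e)
    return float(-0.5 * z.sum() - 0.5 * T * math.log(det) - T * math.log(2 * math.pi))


def log_prior_blocks(params: Parameters, spec: ModelSpec) -> dict[str, float]:
    """Per-block log prior densities; -inf surfaces in the affected block."""
    pr = spec.priors
    sm = spec.submodels
    blocks: dict[str, float] = {}

    if pr.beta0_logit_uniform:
        # uniform on the probability scale: density sigma(b)(1-sigma(b)) on logit
        b = params.beta0
        blocks["beta0"] = float(np.sum(-2.0 * np.logaddexp(0.0, -b) - b))
    else:
        blocks["beta0"] = float(_normal_logpdf(params.beta0, pr.beta0_sd).sum())
    blocks["beta_t"] = float(_normal_logpdf(params.beta_t, pr.slope_sd).sum())
    blocks["beta_e"] = float(_normal_logpdf(params.beta_e, pr.slope_sd).sum())

    lo, hi = pr.theta_bounds
    if sm.n_thresholded:
        if np.any(params.theta < lo) or np.any(params.theta > hi):
            blocks["theta"] = -math.inf
        else:
            blocks["theta"] = -sm.n_thresholded * math.log(hi - lo)
    else:
        blocks["theta"] = 0.0

    if spec.two_axis and sm.n_second_axis:
        pos = sm.beta_f_positive_pos
        if pos is not None and params.beta_f[pos] < 0:
            blocks["beta_f"] = -math.inf
        else:
            blocks["beta_f"] = float(_normal_logpdf(params.beta_f, pr.slope_sd).sum())
    else:
        blocks["beta_f"] = 0.0

    blocks["alpha_t"] = float(_normal_logpdf(params.alpha_t, pr.slope_sd))

    clim = 0.0
    for term in spec.climate_terms:
        coef = np.atleast_1d(np.asarray(params.climate[term.name], dtype=float))
        clim += float(_normal_logpdf(coef, pr.slope_sd).sum())
    blocks["climate"] = clim

    if params.sigma_e <= 0:
        blocks["sigma_e"] = -math.inf
    else:
        sc = pr.sigma_e_scale
        blocks["sigma_e"] = (LOG_HALF_NORMAL_CONST - math.log(sc)
                             - 0.5 * (params.sigma_e / sc) ** 2)

    if spec.two_axis:
        blocks["rho_ef"] = -math.inf if abs(params.rho_ef) >= 1 else -math.log(2.0)
    else:
        blocks["rho_ef"] = 0.0

    if params.eps_e is not None and np.isfinite(blocks["sigma_e"]) and np.isfinite(blocks["rho_ef"]):
        blocks["year_effects"] = year_effect_logpdf(
            params.eps_e, params.eps_f if spec.two_axis else None,
            params.sigma_e, params.rho_ef, spec.two_axis)
    else:
        blocks["year_effects"] = 0.0 if params.eps_e is None else -math.inf
    return blocks


def log_prior(params: Parameters, spec: ModelSpec) -> float:
    """Total log prior; -inf (returned, not raised) outside support."""
    total = 0.0
    for v in log_prior_blocks(params, spec).values():
        if v == -math.inf:
            return -math.inf
        total += v
    return total


def log_posterior(panel: DemographicPanel, params: Parameters, spec: ModelSpec) -> float:
    """log likelihood + log prior; -inf propagates from the prior."""
    lp = log_prior(params, spec)
    if lp == -math.inf:
        return -math.inf
    return log_likelihood(panel, params, spec) + lp
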