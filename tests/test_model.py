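"""Linear predictors, likelihood, priors and their composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import binom

import semflm as sf
from semflm import model as m


def make_params(spec, **kw):
    sm = spec.submodels
    base = dict(
        beta0=np.zeros(sm.n), beta_t=np.zeros(sm.n), beta_e=np.zeros(sm.n),
        theta=np.full(sm.n_thresholded, 2.5), beta_f=np.zeros(sm.n_second_axis),
        alpha_t=0.0, sigma_e=0.1, rho_ef=0.0,
    )
    base.update(kw)
    return m.Parameters(**base)


@pytest.fixture(scope="module")
def spec():
    sm = m.SubmodelSpec.standard()
    return m.ModelSpec("baseline_2axis", sm,
                       priors=m.PriorConfig(theta_bounds=(2.0, 3.0)))


# ---------------------------------------------------------------------------
# submodel structure
# ---------------------------------------------------------------------------

def test_standard_structure():
    sm = m.SubmodelSpec.standard()
    assert sm.n == 11
    assert sm.n_thresholded == 5          # survival minus ram lambs
    assert sm.n_second_axis == 3          # lamb/adult repro, adult twinning
    ram_lamb = [s for s in sm.submodels
                if s.process == "survival" and s.age == "lamb" and s.sex == "M"][0]
    assert not ram_lamb.thresholded
    assert sm.beta_f_positive_pos is not None


def test_structure_validation_rejects_wrong_flags():
    subs = m.standard_submodels()
    subs[0] = m.Submodel(0, "survival", "lamb", "F", thresholded=False,
                         second_axis=False)
    with pytest.raises(ValueError, match="threshold flag"):
        m.SubmodelSpec(subs).validate_standard()


# ---------------------------------------------------------------------------
# axis and linear predictors
# ---------------------------------------------------------------------------

def test_axis_value_arithmetic():
    assert m.axis_value(2.0, 0.0, 0.0, 0.0, 0.0) == 2.0
    assert m.axis_value(2.5, 10.0, 0.01, 0.0, 0.05) == pytest.approx(2.35)


def test_linpred_hand_example(spec):
    """beta0=2, beta_e=1.5, theta=2.2, e=3.0 -> eta=0.8, p ~= 0.6900."""
    sub = spec.submodels.submodels[0]  # thresholded
    params = make_params(spec)
    params.beta0[0], params.beta_e[0] = 2.0, 1.5
    params.theta[spec.submodels.theta_position(0)] = 2.2
    eta = m.linpred(sub, params, 3.0, None, 0.0, spec)
    assert eta == pytest.approx(0.8)
    assert expit(eta) == pytest.approx(0.6900, abs=5e-5)


def test_threshold_continuity_and_flat_below(spec):
    sub = spec.submodels.submodels[0]
    params = make_params(spec)
    params.beta0[0], params.beta_t[0], params.beta_e[0] = 1.0, 0.2, 5.0
    th = params.theta[spec.submodels.theta_position(0)]
    at = m.linpred(sub, params, th, None, 1.0, spec)
    just_below = m.linpred(sub, params, th - 1e-12, None, 1.0, spec)
    assert at == just_below  # continuity at the threshold, exact
    # below the threshold the axis has no effect at all
    for e in (th - 0.5, th - 0.1, th - 1e-6):
        assert m.linpred(sub, params, e, None, 1.0, spec) == at


def test_linpred_second_axis_contract(spec):
    params = make_params(spec)
    plain = spec.submodels.submodels[7]     # yearling reproduction, not loaded
    with pytest.raises(ValueError, match="second axis"):
        m.linpred(plain, params, 2.5, 0.3, 0.0, spec)
    loaded = spec.submodels.submodels[6]    # lamb reproduction
    with pytest.raises(ValueError, match="requires eps_f"):
        m.linpred(loaded, params, 2.5, None, 0.0, spec)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(e=st.floats(2.5, 4.0), beta_e=st.floats(0.1, 10.0))
def test_monotone_decreasing_above_threshold(e, beta_e):
    sm = m.SubmodelSpec.standard()
    spec = m.ModelSpec("baseline_2axis", sm, priors=m.PriorConfig(theta_bounds=(2.0, 3.0)))
    params = make_params(spec)
    params.beta_e[0] = beta_e
    th = params.theta[0]
    sub = sm.submodels[0]
    p_at = expit(m.linpred(sub, params, max(e, th), None, 0.0, spec))
    p_further = expit(m.linpred(sub, params, max(e, th) + 0.1, None, 0.0, spec))
    assert p_further < p_at


def test_sign_convention_all_rates_decrease_in_e(spec, default_dataset):
    """Raising e lowers every vital rate with a positive loading."""
    panel = default_dataset["panel"]
    params = make_params(spec, beta0=np.ones(11), beta_e=np.full(11, 2.0),
                         theta=np.full(5, panel.density.min() - 1.0))
    params = params.with_effects(np.zeros(panel.n_years), np.zeros(panel.n_years))
    e0 = m.axis_values(panel, params, spec)
    p0 = expit(m.linpred_matrix(panel, params, spec, e=e0))
    p1 = expit(m.linpred_matrix(panel, params, spec, e=e0 + 0.1))
    assert np.all(p1 < p0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_loglik_single_cell_value():
    """trials=10, successes=7, p=0.5 -> log C(10,7) - 10 log 2 ~= -2.14398."""
    panel, spec = _one_cell_panel(10, 7)
    params = _p_to_params(spec, 0.5)
    expect = math.log(120) - 10 * math.log(2)
    assert m.log_likelihood(panel, params, spec) == pytest.approx(expect, abs=1e-10)
    assert expect == pytest.approx(-2.14398, abs=5e-6)


def _one_cell_panel(trials, successes):
    sub = m.SubmodelSpec([m.Submodel(0, "survival", "adult", "F", False, False)])
    panel = m.DemographicPanel(np.array([2000]), np.array([2.5]),
                               np.array([[trials]]), np.array([[successes]]), sub)
    spec = m.ModelSpec("baseline_1axis", sub,
                       priors=m.PriorConfig(theta_bounds=(2.0, 3.0)))
    return panel, spec


def _p_to_params(spec, p):
    eta = math.log(p) - math.log1p(-p)
    params = make_params(spec, beta0=np.array([eta]), theta=np.zeros(0),
                         beta_f=np.zeros(0))
    return params.with_effects(np.zeros(1))


def test_loglik_zero_trials_contribute_zero(spec, default_dataset):
    panel = default_dataset["panel"]
    empty = m.DemographicPanel(panel.years, panel.density,
                               np.zeros_like(panel.trials),
                               np.zeros_like(panel.successes), panel.submodels)
    params = make_params(spec).with_effects(np.zeros(panel.n_years),
                                            np.zeros(panel.n_years))
    assert m.log_likelihood(empty, params, spec) == 0.0


def test_loglik_certain_event():
    panel, spec = _one_cell_panel(20, 20)
    params = _p_to_params(spec, 1 - 1e-14)
    assert m.log_likelihood(panel, params, spec) == pytest.approx(0.0, abs=1e-9)


def test_loglik_matches_scipy_oracle(default_dataset, default_spec, rng):
    panel = default_dataset["panel"]
    spec = default_spec
    for _ in range(5):
        params = make_params(
            spec,
            beta0=rng.normal(0, 2, 11), beta_t=rng.normal(0, 0.1, 11),
            beta_e=rng.normal(0, 2, 11), theta=rng.uniform(2.6, 2.95, 5),
            beta_f=rng.normal(0, 1, 3), alpha_t=rng.normal(0, 0.02),
        ).with_effects(rng.normal(0, 0.1, panel.n_years),
                       rng.normal(0, 1, panel.n_years))
        p = m.success_probabilities(panel, params, spec)
        oracle = binom.logpmf(panel.successes, panel.trials, p).sum()
        # 1e-10 relative: the absolute scale of the summed log likelihood
        # (1e4-1e5) sits below double resolution at 1e-10 absolute
        assert m.log_likelihood(panel, params, spec) == pytest.approx(
            oracle, rel=1e-10, abs=1e-8)


def test_panel_validation():
    sub = m.SubmodelSpec.standard()
    years = np.arange(2000, 2003)
    with pytest.raises(ValueError, match="successes"):
        m.DemographicPanel(years, np.full(3, 2.5),
                           np.ones((11, 3), dtype=int),
                           np.full((11, 3), 2), sub)


# ---------------------------------------------------------------------------
# prior and posterior
# ---------------------------------------------------------------------------

def test_prior_outside_support(spec):
    params = make_params(spec, sigma_e=-0.5)
    assert m.log_prior(params, spec) == -math.inf
    params = make_params(spec, rho_ef=1.5)
    assert m.log_prior(params, spec) == -math.inf
    params = make_params(spec)
    params.theta[0] = 99.0
    assert m.log_prior(params, spec) == -math.inf
    # negative sign-constrained second-axis loading
    params = make_params(spec)
    params.beta_f[spec.submodels.beta_f_positive_pos] = -0.2
    assert m.log_prior(params, spec) == -math.inf


def test_year_effects_standard_normal_at_zero():
    sm = m.SubmodelSpec.standard()
    spec1 = m.ModelSpec("baseline_1axis", sm,
                        priors=m.PriorConfig(theta_bounds=(2.0, 3.0)))
    T = 12
    params = make_params(spec1, sigma_e=1.0).with_effects(np.zeros(T))
    blocks = m.log_prior_blocks(params, spec1)
    assert blocks["year_effects"] == pytest.approx(T * math.log(1 / math.sqrt(2 * math.pi)))


def test_prior_equals_sum_of_blocks(spec, rng):
    params = make_params(
        spec, beta0=rng.normal(size=11), beta_e=rng.normal(size=11),
        beta_f=np.abs(rng.normal(size=3)), sigma_e=0.3, rho_ef=0.2,
    ).with_effects(rng.normal(0, 0.2, 30), rng.normal(0, 1, 30))
    blocks = m.log_prior_blocks(params, spec)
    assert m.log_prior(params, spec) == pytest.approx(sum(blocks.values()), abs=1e-10)


def test_log_posterior_recomposes(default_dataset, default_spec, rng):
    panel = default_dataset["panel"]
    params = make_params(default_spec, beta0=rng.normal(size=11)) \
        .with_effects(np.zeros(panel.n_years), np.zeros(panel.n_years))
    lp = m.log_posterior(panel, params, default_spec)
    assert lp == pytest.approx(m.log_likelihood(panel, params, default_spec)
                               + m.log_prior(params, default_spec), abs=1e-12)
    params.sigma_e = -1.0
    assert m.log_posterior(panel, params, default_spec) == -math.inf


def test_climate_nesting_reproduces_baseline(default_dataset):
    """flm_climate with gamma = 0 gives exactly the baseline posterior."""
    panel = default_dataset["panel"]
    matrix = default_dataset["matrix"]
    if matrix is None:
        scenario = default_dataset["scenario"]
        series = sf.interpolate_missing(sf.simulate_climate_daily(scenario))
        matrix = sf.center_windows(
            sf.aggregate_windows(series, scenario.years, "fortnight"))
    basis = sf.build_cr_basis(matrix.n_windows, 8)
    term = m.FlmClimateTerm("clim", matrix.years, matrix.values, basis.basis)
    priors = m.PriorConfig.default_for(panel.density)
    spec_flm = m.ModelSpec("flm_climate", panel.submodels, climate_terms=[term],
                           priors=priors)
    spec_base = m.ModelSpec("baseline_2axis", panel.submodels, priors=priors)
    rng = np.random.default_rng(3)
    params = make_params(spec_base, beta0=rng.normal(size=11),
                         beta_e=rng.normal(size=11),
                         beta_f=np.abs(rng.normal(size=3)),
                         theta=rng.uniform(2.65, 2.9, 5)) \
        .with_effects(rng.normal(0, 0.1, 30), rng.normal(0, 1, 30))
    params_flm = m.Parameters(**{**params.__dict__})
    params_flm.climate = {"clim": np.zeros(8)}
    ll_b = m.log_likelihood(panel, params, spec_base)
    ll_f = m.log_likelihood(panel, params_flm, spec_flm)
    assert ll_f == pytest.approx(ll_b, abs=1e-12)
    # the prior only differs by the (finite) gamma normalization constant
    e_b = m.axis_values(panel, params, spec_base)
    e_f = m.axis_values(panel, params_flm, spec_flm)
    np.testing.assert_allclose(e_b, e_f, atol=1e-14)


def test_flm_contribution_matches_double_sum_oracle(rng):
    """Climate term sum_w f_c(w) C_tw equals the naive double sum."""
    years = np.arange(2000, 2010)
    C = rng.normal(size=(10, 42))
    basis = sf.build_cr_basis(42, 8)
    term = m.FlmClimateTerm("c", years, C, basis.basis)
    gamma = rng.normal(size=8)
    fc = sf.eval_flm(basis.with_gamma(gamma))
    oracle = np.array([sum(fc[w] * C[t, w] for w in range(42)) for t in range(10)])
    ours = term.design_for(years) @ gamma
    np.testing.assert_allclose(ours, oracle, atol=1e-10)
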