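"""Shared fixtures: small synthetic worlds and reduced test models.

Expensive MCMC fits are session-scoped so several tests can share one chain.
"""

import numpy as np
import pytest

import semflm as sf
from semflm import model as m


@pytest.fixture(scope="session")
def default_dataset():
    """One realization of the standard 30-year two-axis scenario."""
    scenario = sf.TruthScenario(seed=42)
    data = sf.simulate_dataset(scenario)
    data["scenario"] = scenario
    return data


@pytest.fixture(scope="session")
def default_spec(default_dataset):
    panel = default_dataset["panel"]
    return sf.ModelSpec("baseline_2axis", panel.submodels,
                        priors=sf.PriorConfig.default_for(panel.density))


@pytest.fixture(scope="session")
def fitted_posterior(default_dataset, default_spec):
    """A converged desk-lite fit of the two-axis model, shared across tests."""
    cfg = sf.McmcConfig(n_chains=2, n_burnin=15_000, n_iter=30_000, thin=25, seed=7)
    return sf.run_mcmc(default_dataset["panel"], default_spec, cfg)


def toy_beta_binomial(trials, successes, n_years=None):
    """Intercept-only single-submodel model with a uniform prior on p.

    Freezes every block except the intercepts, giving the conjugate
    Beta-Binomial posterior p ~ Beta(1 + sum s, 1 + sum(n - s)) on the
    probability scale.  ``trials``/``successes`` may be scalars (one year)
    or arrays (one cell per year).
    """
    trials = np.atleast_1d(np.asarray(trials, dtype=int))
    successes = np.atleast_1d(np.asarray(successes, dtype=int))
    T = len(trials) if n_years is None else n_years
    sub = m.SubmodelSpec([m.Submodel(0, "survival", "adult", "F",
                                     thresholded=False, second_axis=False)])
    years = np.arange(2000, 2000 + T)
    panel = m.DemographicPanel(
        years=years,
        density=np.full(T, 2.5),
        trials=trials[None, :],
        successes=successes[None, :],
        submodels=sub,
    )
    priors = m.PriorConfig(theta_bounds=(2.0, 3.0), beta0_logit_uniform=True)
    spec = m.ModelSpec("baseline_1axis", sub, priors=priors,
                       frozen=frozenset({"beta_t", "beta_e", "theta",
                                         "axis", "year_effects", "variance"}))
    return panel, spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
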