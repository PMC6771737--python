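"""Generator: density walk, climate series, latent axes, binomial panel."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import pearsonr

import semflm as sf
from semflm import model as m


def scenario_with(**kw):
    return sf.TruthScenario(**kw)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

class TestDensity:
    def test_zero_noise_is_constant_at_mean(self):
        sc = scenario_with(density_sd_log10=0.0, density_mean_log10=3.0, seed=1)
        ds = sf.simulate_density(sc)
        np.testing.assert_allclose(ds.log10_count, 3.0)
        np.testing.assert_array_equal(ds.count, 1000)  # log10 identity

    def test_monte_carlo_mean(self):
        """Across replicate series the stationary mean matches the scenario."""
        means = []
        for seed in range(1000):
            sc = scenario_with(n_years=5, seed=seed)
            means.append(sf.simulate_density(sc).log10_count.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 2.78) < 3 * se + 1e-3

    def test_rejects_degenerate_population(self):
        sc = scenario_with(density_mean_log10=1.2, density_sd_log10=0.01, seed=0)
        with pytest.raises(ValueError, match="below 30"):
            sf.simulate_density(sc)

    def test_deterministic_given_seed(self):
        a = sf.simulate_density(scenario_with(seed=5))
        b = sf.simulate_density(scenario_with(seed=5))
        np.testing.assert_array_equal(a.log10_count, b.log10_count)


# ---------------------------------------------------------------------------
# daily climate
# ---------------------------------------------------------------------------

class TestClimateDaily:
    def test_all_zero_variance_constant(self):
        sc = scenario_with(
            n_years=3, seed=2,
            climate=sf.ClimateScenario(0.0, 0.0, 0.0, missing_fraction=0.0))
        series = sf.simulate_climate_daily(sc)
        np.testing.assert_allclose(series.values, series.values[0])

    def test_no_missing_when_fraction_zero(self):
        sc = scenario_with(
            n_years=3, seed=2,
            climate=dataclasses.replace(sf.ClimateScenario(), missing_fraction=0.0))
        assert sf.simulate_climate_daily(sc).n_missing == 0

    def test_span_covers_study_design(self):
        sc = scenario_with(n_years=4, start_year=1990, seed=0)
        series = sf.simulate_climate_daily(sc)
        assert series.dates[0] == np.datetime64("1989-01-01")
        assert series.dates[-1] == np.datetime64("1993-07-31")

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            sf.ClimateScenario(missing_fraction=0.7)
        with pytest.raises(ValueError):
            sf.ClimateScenario(daily_noise_sd=-1.0)


# ---------------------------------------------------------------------------
# latent axes
# ---------------------------------------------------------------------------

class TestAxes:
    def test_degenerate_axis_equals_density(self):
        params = sf.default_truth_params()
        params.sigma_e, params.alpha_t = 0.0, 0.0
        sc = scenario_with(seed=3, params=params)
        ds = sf.simulate_density(sc)
        axes = sf.simulate_axes(sc, ds)
        np.testing.assert_allclose(axes.e, ds.log10_count)

    def test_monte_carlo_correlation_of_uncorrelated_pairs(self):
        """sigma diagonal, both variances 1: sample corr within 0.01 of 0."""
        params = sf.default_truth_params()
        params.sigma_e, params.rho_ef = 1.0, 0.0
        sc = scenario_with(n_years=100_000, seed=4, params=params,
                           density_sd_log10=0.0)
        ds = sf.simulate_density(sc)
        axes = sf.simulate_axes(sc, ds)
        r = pearsonr(axes.eps_e, axes.eps_f).statistic
        assert abs(r) < 0.01
        assert abs(axes.eps_e.std() - 1.0) < 0.02
        assert abs(axes.eps_f.std() - 1.0) < 0.02

    def test_null_flm_effect_reduces_to_baseline_axis(self, default_dataset):
        scenario = default_dataset["scenario"]
        series = sf.interpolate_missing(sf.simulate_climate_daily(scenario))
        matrix = sf.center_windows(
            sf.aggregate_windows(series, scenario.years, "fortnight"))
        params_zero = sf.default_truth_params(with_climate=True,
                                              flm_gamma=np.zeros(8))
        sc_zero = dataclasses.replace(scenario, params=params_zero)
        ds = sf.simulate_density(sc_zero)
        with_clim = sf.simulate_axes(sc_zero, ds, matrix)
        without = sf.simulate_axes(dataclasses.replace(scenario), ds)
        np.testing.assert_allclose(with_clim.e, without.e, atol=1e-12)

    def test_climate_enters_only_through_term(self, default_dataset):
        """Axes with and without the FLM truth differ exactly by the term."""
        scenario = default_dataset["scenario"]
        series = sf.interpolate_missing(sf.simulate_climate_daily(scenario))
        matrix = sf.center_windows(
            sf.aggregate_windows(series, scenario.years, "fortnight"))
        gamma = sf.default_flm_gamma()
        sc_c = dataclasses.replace(
            scenario, params=sf.default_truth_params(with_climate=True))
        ds = sf.simulate_density(sc_c)
        ax_c = sf.simulate_axes(sc_c, ds, matrix)
        ax_0 = sf.simulate_axes(dataclasses.replace(scenario), ds)
        fc = sf.eval_flm(sf.build_cr_basis(42, 8).with_gamma(gamma))
        np.testing.assert_allclose(ax_0.e - ax_c.e, matrix.values @ fc, atol=1e-12)

    def test_invalid_covariance(self):
        params = sf.default_truth_params()
        params.rho_ef = 1.0
        with pytest.raises(ValueError):
            scenario_with(seed=0, params=params)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

class TestPanel:
    def test_certain_success(self):
        params = sf.default_truth_params()
        params.beta0 = np.full(11, 40.0)
        params.beta_e = np.zeros(11)
        params.beta_f = np.zeros(3)
        sc = scenario_with(n_years=5, seed=6, params=params)
        ds = sf.simulate_density(sc)
        axes = sf.simulate_axes(sc, ds)
        panel = sf.simulate_panel(sc, axes, ds)
        np.testing.assert_array_equal(panel.successes, panel.trials)

    def test_zero_trial_cells_are_legal(self):
        """Suppressing yearling reproduction empties yearling twinning."""
        params = sf.default_truth_params()
        params.beta0[7] = -30.0  # yearling reproduction never happens
        sc = scenario_with(n_years=6, seed=7, params=params)
        ds = sf.simulate_density(sc)
        axes = sf.simulate_axes(sc, ds)
        panel = sf.simulate_panel(sc, axes, ds)
        assert np.all(panel.trials[9] == 0)       # yearling twinning
        assert np.all(panel.successes[9] == 0)
        panel_check = m.DemographicPanel(panel.years, panel.density,
                                         panel.trials, panel.successes,
                                         panel.submodels)  # validates

    def test_binomial_law_monte_carlo(self):
        """Empirical frequency over replicate panels matches the cell p."""
        sc0 = scenario_with(n_years=3, seed=0)
        ds = sf.simulate_density(sc0)
        axes = sf.simulate_axes(sc0, ds)
        sub_j, year_i = 4, 1  # adult female survival, middle year
        spec = m.ModelSpec("baseline_2axis", sc0.submodel_spec,
                           priors=m.PriorConfig.default_for(ds.log10_count))
        params = sc0.params.with_effects(axes.eps_e, axes.eps_f)
        stub = m.DemographicPanel(sc0.years, ds.log10_count,
                                  np.zeros((11, 3), dtype=int),
                                  np.zeros((11, 3), dtype=int), sc0.submodel_spec)
        p = expit(m.linpred_matrix(stub, params, spec, e=axes.e))[sub_j, year_i]
        freqs = []
        for seed in range(2000):
            panel = sf.simulate_panel(dataclasses.replace(sc0, seed=seed), axes, ds)
            freqs.append(panel.successes[sub_j, year_i] / panel.trials[sub_j, year_i])
        freqs = np.asarray(freqs)
        n_tr = panel.trials[sub_j, year_i]
        se = np.sqrt(p * (1 - p) / n_tr) / np.sqrt(len(freqs))
        assert abs(freqs.mean() - p) < 3 * se

    def test_trial_bookkeeping(self, default_dataset):
        """Fecundity trials chain off the survival and reproduction draws."""
        panel = default_dataset["panel"]
        labels = panel.submodels.labels
        i = {l: j for j, l in enumerate(labels)}
        np.testing.assert_array_equal(panel.trials[i["repro_lamb_f"]],
                                      panel.successes[i["surv_lamb_f"]])
        np.testing.assert_array_equal(panel.trials[i["twin_adult_f"]],
                                      panel.successes[i["repro_adult_f"]])

    def test_bit_identical_given_seed(self):
        a = sf.simulate_dataset(scenario_with(seed=11))
        b = sf.simulate_dataset(scenario_with(seed=11))
        np.testing.assert_array_equal(a["panel"].successes, b["panel"].successes)
        np.testing.assert_array_equal(a["panel"].trials, b["panel"].trials)
        np.testing.assert_array_equal(a["density"].log10_count,
                                      b["density"].log10_count)
        vals_a, vals_b = a["daily"].values, b["daily"].values
        np.testing.assert_array_equal(np.isnan(vals_a), np.isnan(vals_b))
        np.testing.assert_array_equal(vals_a[~np.isnan(vals_a)],
                                      vals_b[~np.isnan(vals_b)])

    def test_piecewise_shape_recovered_at_large_trials(self):
        """Thresholded survival is flat below theta and declining above."""
        params = sf.default_truth_params()
        sc = scenario_with(
            n_years=30, seed=13, params=params,
            density_mean_log10=np.log10(60_000 / 600) + 2.78,  # ~1e4 per class
            density_sd_log10=0.12)
        # keep thresholds inside the shifted density range
        shift = sc.density_mean_log10 - 2.78
        params.theta = params.theta + shift
        ds = sf.simulate_density(sc)
        axes = sf.simulate_axes(sc, ds)
        panel = sf.simulate_panel(sc, axes, ds)
        j = 0  # lamb female survival, thresholded
        th = params.theta[0]
        prop = panel.successes[j] / panel.trials[j]
        below, above = axes.e < th, axes.e >= th
        assert below.sum() >= 5 and above.sum() >= 5
        # below: no association with e at the 1% level
        r_below = pearsonr(axes.e[below], prop[below])
        assert r_below.pvalue > 0.01
        # above: strongly decreasing
        r_above = pearsonr(axes.e[above], prop[above])
        assert r_above.statistic < 0 and r_above.pvalue < 0.01


def test_scenario_validation():
    with pytest.raises(ValueError):
        scenario_with(n_years=2)
    with pytest.raises(ValueError):
        scenario_with(class_fractions=np.full(6, 0.3))  # sums over 1
    with pytest.raises(ValueError):
        scenario_with(density_ar1=1.5)
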