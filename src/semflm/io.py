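"""CSV/YAML readers and writers for every pipeline artifact.

All outputs are plain text and round-trip losslessly through the package's
own readers (full float precision via repr).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import model as m
from .climate import ClimateMatrix, DailyClimateSeries
from .mcmc import McmcConfig, Posterior
from .synthetic import ClimateScenario, DensitySeries, TruthScenario

__all__ = [
    "write_panel", "read_panel", "write_density", "read_density",
    "write_daily", "read_daily", "write_matrix", "read_matrix",
    "write_posterior", "read_posterior", "write_scenario", "read_scenario",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def write_panel(panel: m.DemographicPanel, path) -> None:
    rows = []
    for j in range(panel.submodels.n):
        for i, year in enumerate(panel.years):
            rows.append((int(year), j, panel.submodels.labels[j],
                         int(panel.trials[j, i]), int(panel.successes[j, i])))
    df = pd.DataFrame(rows, columns=["year", "submodel_id", "submodel",
                                     "trials", "successes"])
    df.to_csv(path, index=False)


def read_panel(panel_path, density_path,
               submodels: Optional[m.SubmodelSpec] = None) -> m.DemographicPanel:
    if submodels is None:
        submodels = m.SubmodelSpec.standard()
    density = read_density(density_path)
    df = pd.read_csv(panel_path)
    years = density.years
    T = len(years)
    trials = np.zeros((submodels.n, T), dtype=int)
    successes = np.zeros((submodels.n, T), dtype=int)
    year_pos = {int(y): i for i, y in enumerate(years)}
    for r in df.itertuples():
        trials[int(r.submodel_id), year_pos[int(r.year)]] = int(r.trials)
        successes[int(r.submodel_id), year_pos[int(r.year)]] = int(r.successes)
    return m.DemographicPanel(years, density.log10_count, trials, successes, submodels)


def write_density(ds: DensitySeries, path) -> None:
    pd.DataFrame({"year": ds.years,
                  "log10_count": ds.log10_count,
                  "count": ds.count}).to_csv(path, index=False,
                                             float_format=_FLOAT_FMT)


def read_density(path) -> DensitySeries:
    df = pd.read_csv(path)
    return DensitySeries(df["year"].to_numpy(), df["log10_count"].to_numpy(),
                         df["count"].to_numpy())


def write_daily(series: DailyClimateSeries, path) -> None:
    pd.DataFrame({
        "date": series.dates.strftime("%Y-%m-%d"),
        "value": series.values,
        "missing": np.isnan(series.values).astype(int),
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_daily(path, variable_name: str = "climate") -> DailyClimateSeries:
    df = pd.read_csv(path)
    values = df["value"].to_numpy(dtype=float)
    if "missing" in df.columns:
        values = np.where(df["missing"].to_numpy() == 1, np.nan, values)
    return DailyClimateSeries(pd.DatetimeIndex(pd.to_datetime(df["date"])),
                              values, variable_name)


def write_matrix(matrix: ClimateMatrix, path) -> None:
    path = Path(path)
    header = (f"# scheme={matrix.window_scheme} centered={matrix.centered} "
              f"variable={matrix.variable_name}\n")
    df = pd.DataFrame(matrix.values,
                      columns=[f"w{j + 1}" for j in range(matrix.n_windows)])
    df.insert(0, "year", matrix.years)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_matrix(path) -> ClimateMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    meta = {}
    if first.startswith("#"):
        for tok in first.lstrip("#").split():
            k, _, v = tok.partition("=")
            meta[k] = v
    df = pd.read_csv(path, comment="#")
    years = df["year"].to_numpy(dtype=int)
    values = df.drop(columns="year").to_numpy(dtype=float)
    return ClimateMatrix(years, values,
                         window_scheme=meta.get("scheme", "fortnight"),
                         variable_name=meta.get("variable", "climate"),
                         centered=meta.get("centered", "False") == "True")


def write_posterior(post: Posterior, path) -> None:
    post.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_posterior(path, spec: Optional[m.ModelSpec] = None,
                   years: Optional[np.ndarray] = None,
                   config: Optional[McmcConfig] = None) -> Posterior:
    df = pd.read_csv(path)
    chains = df["chain"].to_numpy(dtype=int)
    names = [c for c in df.columns if c != "chain"]
    draws = df[names].to_numpy(dtype=float)
    if years is None:
        years = np.array(sorted({int(n[6:-1]) for n in names
                                 if n.startswith("eps_e[")}))
    return Posterior(draws, chains, names, spec, np.asarray(years),
                     config or McmcConfig())


# ---------------------------------------------------------------------------
# Scenario and manifest
# ---------------------------------------------------------------------------

def _params_to_dict(p: m.Parameters) -> dict:
    return {
        "beta0": p.beta0.tolist(),
        "beta_t": p.beta_t.tolist(),
        "beta_e": p.beta_e.tolist(),
        "theta": p.theta.tolist(),
        "beta_f": p.beta_f.tolist(),
        "alpha_t": float(p.alpha_t),
        "sigma_e": float(p.sigma_e),
        "rho_ef": float(p.rho_ef),
        "climate": {k: np.atleast_1d(v).tolist() for k, v in p.climate.items()},
    }


def _params_from_dict(d: dict) -> m.Parameters:
    return m.Parameters(
        beta0=np.array(d["beta0"]), beta_t=np.array(d["beta_t"]),
        beta_e=np.array(d["beta_e"]), theta=np.array(d["theta"]),
        beta_f=np.array(d["beta_f"]), alpha_t=d["alpha_t"],
        sigma_e=d["sigma_e"], rho_ef=d["rho_ef"],
        climate={k: np.array(v) for k, v in d.get("climate", {}).items()},
    )


def write_scenario(scenario: TruthScenario, path) -> None:
    doc = {
        "n_years": scenario.n_years,
        "start_year": scenario.start_year,
        "density_mean_log10": scenario.density_mean_log10,
        "density_sd_log10": scenario.density_sd_log10,
        "density_ar1": scenario.density_ar1,
        "class_fractions": scenario.class_fractions.tolist(),
        "n_flm_knots": scenario.n_flm_knots,
        "seed": scenario.seed,
        "climate": {
            "seasonal_amplitude": scenario.climate.seasonal_amplitude,
            "daily_noise_sd": scenario.climate.daily_noise_sd,
            "yearly_anomaly_sd": scenario.climate.yearly_anomaly_sd,
            "missing_fraction": scenario.climate.missing_fraction,
        },
        "params": _params_to_dict(scenario.params),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_scenario(path) -> TruthScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return TruthScenario(
        n_years=doc["n_years"],
        start_year=doc["start_year"],
        params=_params_from_dict(doc["params"]),
        density_mean_log10=doc["density_mean_log10"],
        density_sd_log10=doc["density_sd_log10"],
        density_ar1=doc["density_ar1"],
        class_fractions=np.array(doc["class_fractions"]),
        climate=ClimateScenario(**doc["climate"]),
        n_flm_knots=doc["n_flm_knots"],
        seed=doc["seed"],
    )


def write_manifest(path, **entries) -> None:
    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    with open(path, "w") as fh:
        json.dump({k: clean(v) for k, v in entries.items()}, fh, indent=2)
        fh.write("\n")
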