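"""Orchestration of the three experiments: historical, validation, climate.

Each ``run_*`` function is a thin composition of the library stages that
writes tidy CSV/JSON outputs plus a manifest (seeds, counts, versions) to
an output directory and returns its result bundle.  The command-line
interface in :mod:`mimicslite.cli` wraps these functions.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import (
    evaluate_sets,
    filter_sets,
    records_to_frame,
    sample_parameter_sets,
    select_best,
    stability_check,
)
from .climate import climate_response, driver_analysis
from .effects import fit_mass_loss_model
from .forcing import DailyForcing, SiteForcing, load_sites
from .litterbag import run_design
from .params import (
    CalibrationMultiplierSet,
    KineticParameters,
    default_parameters,
    load_calibrated_sets,
    load_parameters,
)
from .synthetic import (
    generate_anomalies,
    generate_daily_forcing,
    generate_model_observations,
    generate_observations,
)

__all__ = [
    "daily_forcings_for",
    "run_historical",
    "run_validation",
    "run_calibration",
    "run_climate",
]


def daily_forcings_for(sites: list[SiteForcing], seed: int) -> dict[str, DailyForcing]:
    """One seeded daily climatology per site (seed offset by site order)."""
    return {
        site.site_id: generate_daily_forcing(site, seed=seed + i)
        for i, site in enumerate(sites)
    }


def _manifest(outdir: Path, name: str, seed: int, extra: dict) -> None:
    manifest = {
        "experiment": name,
        "package_version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _params(params_file: str | None) -> KineticParameters:
    return load_parameters(params_file) if params_file else default_parameters()


def run_historical(
    outdir: str | Path,
    *,
    seed: int = 0,
    site_table: str | None = None,
    params_file: str | None = None,
    calibrated: bool = True,
) -> dict:
    """Historical experiment: steady states, the 63-run litterbag design,
    and effect sizes for the default (and optionally calibrated) model."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _params(params_file)
    sites = load_sites(site_table, role="calibration")
    daily = daily_forcings_for(sites, seed)

    mult_sets: list[CalibrationMultiplierSet | None] = [None]
    if calibrated:
        mult_sets += load_calibrated_sets()

    tables, effects = [], {}
    for ms in mult_sets:
        label = "default" if ms is None else f"set{ms.draw_id}"
        table = run_design(sites, daily, params, mults=ms)
        table["model"] = label
        table["plot"] = (
            table["site"] + "-" + table["litter_id"].astype(str) + "-" + table["moisture_variant"]
        )
        table["co_ratio"] = np.minimum(table["co_ratio"], 1e3)
        tables.append(table)
        res = fit_mass_loss_model(table)
        effects[label] = res.relative.round(2).to_dict()
    full = pd.concat(tables, ignore_index=True)
    full.to_csv(outdir / "historical_runs.csv", index=False)
    pd.DataFrame(effects).to_csv(outdir / "historical_effect_sizes.csv")
    n_default = int((full["model"] == "default").sum()) // 2  # two timepoints per run
    _manifest(outdir, "historical", seed, {
        "n_sites": len(sites),
        "n_default_runs": n_default,
        "n_models": len(mult_sets),
    })
    return {"runs": full, "effects": effects, "n_default_runs": n_default}


def run_validation(
    outdir: str | Path,
    *,
    seed: int = 0,
    site_table: str | None = None,
    params_file: str | None = None,
    observations: str | None = None,
) -> dict:
    """Validation experiment on the held-out sites.

    Field observations may be supplied as a CSV with columns site,
    timepoint, mass_loss_pct; otherwise synthetic observations are
    generated from the default model plus noise (and labelled as such).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _params(params_file)
    sites = load_sites(site_table, role="validation")
    daily = daily_forcings_for(sites, seed + 1000)

    if observations is not None:
        obs = pd.read_csv(observations)
        obs_means = obs.groupby(["site", "timepoint"])["mass_loss_pct"].mean()
        obs_source = "file"
    else:
        obs_table, envelope, _ = generate_model_observations(
            sites, daily, params, CalibrationMultiplierSet.identity(), seed=seed + 2000
        )
        obs_means = envelope.set_index(["site", "timepoint"])["obs_mean"]
        obs_source = "synthetic (default model + noise)"

    rows, tables = [], []
    for ms in [None] + load_calibrated_sets():
        label = "default" if ms is None else f"set{ms.draw_id}"
        table = run_design(sites, daily, params, mults=ms)
        table["model"] = label
        tables.append(table)
        sim = table.groupby(["site", "timepoint"])["mass_loss_pct"].mean()
        err = float(np.sqrt(np.mean((sim - obs_means.reindex(sim.index)) ** 2)))
        rows.append({"model": label, "rmse_vs_obs": err})
    full = pd.concat(tables, ignore_index=True)
    full.to_csv(outdir / "validation_runs.csv", index=False)
    gof = pd.DataFrame(rows)
    gof.to_csv(outdir / "validation_gof.csv", index=False)
    _manifest(outdir, "validation", seed, {
        "n_sites": len(sites),
        "observations": obs_source,
        "runs_per_model": int(len(full) / len(gof) / 2),
    })
    return {"runs": full, "gof": gof}


def run_calibration(
    outdir: str | Path,
    *,
    seed: int = 0,
    n_draws: int = 500,
    site_table: str | None = None,
    params_file: str | None = None,
    observations: str | None = None,
    rmse_max: float = 5.4,
    effect_tol: float = 10.0,
    k: int = 3,
    stability_replicates: int = 100,
    truth_set: CalibrationMultiplierSet | None = None,
    progress: bool = False,
) -> dict:
    """Monte Carlo calibration against observed (or synthetic) mass loss.

    With no observation file, a synthetic truth experiment is run: the
    "observations" come from the model under ``truth_set`` (the first
    packaged calibrated multiplier set by default) plus noise, making the
    whole loop self-consistent and the truth recoverable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _params(params_file)
    sites = load_sites(site_table, role="calibration")
    daily = daily_forcings_for(sites, seed)

    if observations is not None:
        obs_table = pd.read_csv(observations)
        envelope = (
            obs_table.groupby(["site", "timepoint"])["mass_loss_pct"]
            .agg(obs_min="min", obs_mean="mean", obs_max="max")
            .reset_index()
        )
        truth = None
    else:
        truth = truth_set or load_calibrated_sets()[0]
        obs_table, envelope, _ = generate_model_observations(
            sites, daily, params, truth, seed=seed + 5000
        )
    observed_effects = fit_mass_loss_model(obs_table).relative

    draws = sample_parameter_sets(n_draws, seed=seed)
    records = evaluate_sets(draws, sites, daily, params, progress=progress)
    scored = filter_sets(records, envelope, observed_effects,
                         rmse_max=rmse_max, effect_tol=effect_tol)
    scored.to_csv(outdir / "calibration_scored.csv", index=False)
    best = select_best(scored, k=k)
    best.to_csv(outdir / "calibration_best.csv", index=False)
    stability = stability_check(
        records, envelope, observed_effects, replicates=stability_replicates,
        seed=seed + 1, rmse_max=rmse_max, effect_tol=effect_tol, k=k,
    )
    (outdir / "calibration_top.json").write_text(
        json.dumps(
            {
                "best": best.to_dict(orient="records"),
                "stability": stability,
                "observed_effects": observed_effects.round(3).to_dict(),
                "truth": truth.as_dict() if truth else None,
            },
            indent=2,
        )
    )
    _manifest(outdir, "calibration", seed, {
        "n_draws": n_draws,
        "n_survivors": int(scored["survives"].sum()),
        "rmse_max": rmse_max,
        "effect_tol": effect_tol,
    })
    return {
        "scored": scored,
        "best": best,
        "stability": stability,
        "observed_effects": observed_effects,
        "records": records,
        "envelope": envelope,
        "truth": truth,
    }


def run_climate(
    outdir: str | Path,
    *,
    seed: int = 0,
    site_table: str | None = None,
    params_file: str | None = None,
    anomaly_file: str | None = None,
) -> dict:
    """Climate experiment: anomaly-forced future runs, per-run responses,
    and the mixed-model driver analysis of the calibration effect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _params(params_file)
    sites = load_sites(site_table, role="calibration")
    daily = daily_forcings_for(sites, seed)
    anomaly = (
        pd.read_csv(anomaly_file) if anomaly_file else generate_anomalies(seed=seed + 42)
    )
    response = climate_response(sites, daily, anomaly, params, load_calibrated_sets())
    response.to_csv(outdir / "climate_response.csv", index=False)
    drivers = driver_analysis(response)
    pd.DataFrame(drivers).to_csv(outdir / "climate_drivers.csv")
    _manifest(outdir, "climate", seed, {
        "n_rows": len(response),
        "anomaly_source": anomaly_file or "synthetic",
    })
    return {"response": response, "drivers": drivers}
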