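"""Monte Carlo calibration of the four kinetic multipliers.

Random multiplier sets (independent uniform draws within their ranges) are
each pushed through the full factorial litterbag design; a set survives the
screening when it (1) keeps every site's mean simulated mass loss inside
the observed min-max envelope at both timepoints, (2) lands all three
relative effect sizes within a tolerance (10 percentage points by default)
of the observed ones, (3) achieves a mass-loss RMSE below a threshold
(5.4% by default) over site x timepoint means, and (4) maintains a viable
copiotrophic or oligotrophic microbial group in every run.  Survivors are
ranked by RMSE (mass-loss fit is prioritized over effect-size fit, which
breaks ties), and the top three form the calibrated model.

Because a draw's simulations are independent of the observations, records
are evaluated once and can be re-screened cheaply against alternative
observation sets (the leave-10%-out stability check exploits the same
separation).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .effects import fit_mass_loss_model
from .forcing import DailyForcing, SiteForcing
from .litterbag import run_design
from .params import (
    MULTIPLIER_RANGES,
    CalibrationMultiplierSet,
    KineticParameters,
)

__all__ = [
    "EvaluationRecord",
    "sample_parameter_sets",
    "evaluate_set",
    "evaluate_sets",
    "rmse",
    "filter_sets",
    "select_best",
    "stability_check",
    "records_to_frame",
    "CalibrationError",
]

RMSE_MAX_DEFAULT = 5.4
EFFECT_TOL_DEFAULT = 10.0


class CalibrationError(RuntimeError):
    pass


@dataclasses.dataclass
class EvaluationRecord:
    """One evaluated multiplier set.

    ``site_means`` holds mean simulated mass loss per (site, timepoint);
    ``relative_effects`` the three relativized model coefficients;
    ``viable`` whether every run kept at least one microbial group above
    the viability floor.  RMSE and filter verdicts are computed against a
    particular observation set by :func:`filter_sets`.
    """

    mults: CalibrationMultiplierSet
    site_means: pd.Series  # index (site, timepoint)
    relative_effects: pd.Series  # index z_moisture, z_lignin_n, z_co_ratio
    viable: bool
    failed: bool = False
    failure: str = ""


def sample_parameter_sets(
    n: int = 5000,
    ranges: dict[str, tuple[float, float]] = MULTIPLIER_RANGES,
    seed: int = 0,
) -> list[CalibrationMultiplierSet]:
    """Independent uniform draws of the four multipliers."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"invalid range for {name}: [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    draws = {name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in ranges.items()}
    return [
        CalibrationMultiplierSet(
            m_tau_r=float(draws["m_tau_r"][i]),
            m_beta=float(draws["m_beta"][i]),
            m_vmod_m=float(draws["m_vmod_m"][i]),
            m_vmod_s=float(draws["m_vmod_s"][i]),
            draw_id=i,
        )
        for i in range(n)
    ]


def evaluate_set(
    mults: CalibrationMultiplierSet,
    sites: list[SiteForcing],
    daily_forcings: dict[str, DailyForcing],
    params: KineticParameters,
) -> EvaluationRecord:
    """Run the full design under one multiplier set and summarize it."""
    try:
        table = run_design(sites, daily_forcings, params, mults=mults)
    except Exception as exc:  # solver failures are recorded, not dropped
        return EvaluationRecord(
            mults=mults,
            site_means=pd.Series(dtype=float),
            relative_effects=pd.Series(dtype=float),
            viable=False,
            failed=True,
            failure=str(exc),
        )
    table = table.copy()
    table["plot"] = (
        table["site"] + "-" + table["litter_id"].astype(str) + "-" + table["moisture_variant"]
    )
    table["co_ratio"] = np.minimum(table["co_ratio"], 1e3)
    site_means = table.groupby(["site", "timepoint"])["mass_loss_pct"].mean()
    viable = bool((table["viable_r"] | table["viable_k"]).all())
    try:
        effects = fit_mass_loss_model(table).relative
    except Exception as exc:
        return EvaluationRecord(mults, site_means, pd.Series(dtype=float), viable,
                                failed=True, failure=f"effect-size fit: {exc}")
    return EvaluationRecord(mults, site_means, effects, viable)


def evaluate_sets(
    mult_sets: list[CalibrationMultiplierSet],
    sites: list[SiteForcing],
    daily_forcings: dict[str, DailyForcing],
    params: KineticParameters,
    *,
    progress: bool = False,
) -> list[EvaluationRecord]:
    """Evaluate many sets; each draw is independent of every other."""
    records = []
    for i, mults in enumerate(mult_sets):
        records.append(evaluate_set(mults, sites, daily_forcings, params))
        if progress and (i + 1) % 50 == 0:
            print(f"  evaluated {i + 1}/{len(mult_sets)} parameter sets")
    return records


def rmse(simulated: pd.Series, observed: pd.Series) -> float:
    """Root mean squared error over aligned site x timepoint means."""
    obs = observed.reindex(simulated.index)
    if obs.isna().any():
        raise ValueError("observed means missing for some site x timepoint cells")
    return float(np.sqrt(np.mean((simulated.to_numpy() - obs.to_numpy()) ** 2)))


def _envelope_series(envelope: pd.DataFrame):
    env = envelope.set_index(["site", "timepoint"])
    return env["obs_min"], env["obs_mean"], env["obs_max"]


def filter_sets(
    records: list[EvaluationRecord],
    envelope: pd.DataFrame,
    observed_effects: pd.Series,
    *,
    rmse_max: float = RMSE_MAX_DEFAULT,
    effect_tol: float | dict[str, float] = EFFECT_TOL_DEFAULT,
) -> pd.DataFrame:
    """Score every record against the observations and apply the four
    screening criteria.

    ``envelope`` needs columns site, timepoint, obs_min, obs_mean, obs_max;
    ``observed_effects`` the three observed relative effect sizes indexed
    like the model ones.  ``effect_tol`` may be one tolerance or one per
    driver.  Returns one row per record with per-criterion verdicts, RMSE,
    effect deviation, and ``survives``.
    """
    obs_min, obs_mean, obs_max = _envelope_series(envelope)
    if isinstance(effect_tol, dict):
        tol = pd.Series(effect_tol).reindex(observed_effects.index)
        if tol.isna().any():
            raise ValueError("effect_tol missing entries for some drivers")
    else:
        tol = pd.Series(float(effect_tol), index=observed_effects.index)

    rows = []
    for rec in records:
        if rec.failed or rec.site_means.empty or rec.relative_effects.empty:
            rows.append(
                {
                    "draw_id": rec.mults.draw_id,
                    **rec.mults.as_dict(),
                    "rmse": np.nan,
                    "effect_dev": np.nan,
                    "in_envelope": False,
                    "effects_close": False,
                    "rmse_ok": False,
                    "viable": rec.viable,
                    "survives": False,
                    "failed": True,
                }
            )
            continue
        sim = rec.site_means
        in_env = bool(
            ((sim >= obs_min.reindex(sim.index)) & (sim <= obs_max.reindex(sim.index))).all()
        )
        dev = (rec.relative_effects - observed_effects.reindex(rec.relative_effects.index)).abs()
        effects_close = bool((dev <= tol.reindex(dev.index)).all())
        err = rmse(sim, obs_mean)
        rows.append(
            {
                "draw_id": rec.mults.draw_id,
                **rec.mults.as_dict(),
                "rmse": err,
                "effect_dev": float(dev.sum()),
                "in_envelope": in_env,
                "effects_close": effects_close,
                "rmse_ok": err < rmse_max,
                "viable": rec.viable,
                "survives": in_env and effects_close and err < rmse_max and rec.viable,
                "failed": False,
            }
        )
    return pd.DataFrame(rows)


def select_best(scored: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Rank survivors by RMSE (ties broken by summed absolute effect-size
    deviation) and return the top ``k``."""
    survivors = scored[scored["survives"]].copy()
    if survivors.empty:
        raise CalibrationError(
            "no parameter set survived all four criteria; consider loosening "
            "rmse_max or effect_tol"
        )
    survivors = survivors.sort_values(["rmse", "effect_dev", "draw_id"]).reset_index(drop=True)
    if k > len(survivors):
        import warnings

        warnings.warn(f"only {len(survivors)} survivors for requested top {k}")
    return survivors.head(k)


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Flatten records (multipliers, effects, viability) for CSV export."""
    rows = []
    for rec in records:
        row = {"draw_id": rec.mults.draw_id, **rec.mults.as_dict(),
               "viable": rec.viable, "failed": rec.failed, "failure": rec.failure}
        for key, val in rec.relative_effects.items():
            row[f"rel_{key}"] = val
        for (site, tp), val in rec.site_means.items():
            row[f"sim_{site}_t{tp}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def closed_loop_recovery(
    sites: list[SiteForcing],
    daily_forcings: dict[str, DailyForcing],
    params: KineticParameters,
    truth: CalibrationMultiplierSet,
    *,
    n_pool: int = 2000,
    n_draws: int = 500,
    replicates: int = 20,
    neighborhood: float = 0.15,
    k: int = 3,
    seed: int = 0,
    noise_sd: float = 1.5,
    rmse_max: float = RMSE_MAX_DEFAULT,
    effect_tol: float | dict[str, float] = EFFECT_TOL_DEFAULT,
    progress: bool = False,
) -> dict:
    """End-to-end calibration recovery against a known multiplier set.

    Synthetic observations are generated from the model under ``truth``
    plus seeded noise.  A pool of ``n_pool`` multiplier sets is evaluated
    once (each draw's simulations are observation-independent); every
    replicate then re-noises the observations and screens a fresh random
    ``n_draws``-subset of the pool.  A replicate succeeds when at least
    one of its top-``k`` selections lies within ``neighborhood`` (relative,
    per multiplier) of the truth.
    """
    from .synthetic import generate_model_observations

    pool = sample_parameter_sets(n_pool, seed=seed)
    records = evaluate_sets(pool, sites, daily_forcings, params, progress=progress)
    truth_vec = np.array(list(truth.as_dict().values()))
    names = list(truth.as_dict().keys())

    successes, n_selected = 0, []
    rng = np.random.default_rng(seed + 1)
    for rep in range(replicates):
        obs, envelope, _ = generate_model_observations(
            sites, daily_forcings, params, truth, seed=seed + 100 + rep, noise_sd=noise_sd
        )
        observed_effects = fit_mass_loss_model(obs).relative
        idx = rng.choice(n_pool, size=min(n_draws, n_pool), replace=False)
        subset = [records[i] for i in idx]
        try:
            best = select_best(
                filter_sets(subset, envelope, observed_effects,
                            rmse_max=rmse_max, effect_tol=effect_tol),
                k=k,
            )
        except CalibrationError:
            n_selected.append(0)
            continue
        sel = best[names].to_numpy()
        rel_dev = np.abs(sel - truth_vec) / truth_vec
        successes += bool((rel_dev <= neighborhood).all(axis=1).any())
        n_selected.append(len(best))
    return {
        "success_fraction": successes / replicates,
        "replicates": replicates,
        "mean_selected": float(np.mean(n_selected)),
        "neighborhood": neighborhood,
        "truth": truth.as_dict(),
    }


def stability_check(
    records: list[EvaluationRecord],
    envelope: pd.DataFrame,
    observed_effects: pd.Series,
    *,
    holdout: float = 0.10,
    replicates: int = 100,
    k: int = 3,
    seed: int = 0,
    rmse_max: float = RMSE_MAX_DEFAULT,
    effect_tol: float | dict[str, float] = EFFECT_TOL_DEFAULT,
) -> dict:
    """Re-select on random (1 - holdout) subsets of the evaluated runs.

    Reports the fraction of replicates whose top-k selection exactly
    matches the full-data selection, and the mean overlap fraction.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records for a stability check")
    full = select_best(
        filter_sets(records, envelope, observed_effects, rmse_max=rmse_max, effect_tol=effect_tol),
        k,
    )
    full_ids = set(full["draw_id"])
    rng = np.random.default_rng(seed)
    n_keep = int(round((1.0 - holdout) * len(records)))
    exact, overlap = 0, 0.0
    for _ in range(replicates):
        idx = rng.choice(len(records), size=n_keep, replace=False)
        subset = [records[i] for i in idx]
        try:
            sel = select_best(
                filter_sets(subset, envelope, observed_effects,
                            rmse_max=rmse_max, effect_tol=effect_tol),
                k,
            )
            ids = set(sel["draw_id"])
        except CalibrationError:
            ids = set()
        exact += ids == full_ids
        overlap += len(ids & full_ids) / max(len(full_ids), 1)
    return {
        "full_selection": sorted(full_ids),
        "exact_match_fraction": exact / replicates,
        "mean_overlap_fraction": overlap / replicates,
        "replicates": replicates,
        "holdout": holdout,
    }
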