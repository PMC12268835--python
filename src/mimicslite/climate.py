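"""Anomaly-forced climate-change experiment.

Monthly anomalies (soil-temperature deltas, additive moisture-scalar deltas
clipped to keep the scalar in [0, 1], and a litterfall multiplier) are added
to the historical daily climatology to produce future forcing for a target
window (2072-2074 by default).  Both the default and the calibrated models
are re-run under historical and future forcing; the climate response of a
run is the change in litterbag mass loss (future minus historical) at each
collection timepoint, and the calibration effect is the percent difference
between the calibrated (mean over the three best multiplier sets) and
default responses.  A mixed model then attributes that difference to site
and plot covariates in three variants (historical levels, future levels, or
their deltas).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .forcing import DailyForcing, SiteForcing
from .litterbag import run_design
from .params import CalibrationMultiplierSet, KineticParameters

__all__ = [
    "apply_anomalies",
    "future_forcing",
    "climate_response",
    "driver_analysis",
    "PERCENT_DIFF_GUARD",
]

#: |default response| below this (percentage points of mass loss) switches
#: the difference metric from percent to absolute, flagged in the output.
PERCENT_DIFF_GUARD = 0.1

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_DAY_MONTH = np.repeat(np.arange(1, 13), _MONTH_DAYS)  # day-of-year -> month


def apply_anomalies(daily: DailyForcing, anomaly: pd.DataFrame, year: int) -> DailyForcing:
    """Apply one year of monthly anomalies to a daily climatology.

    ``anomaly`` needs columns year, month, d_temp, d_moisture,
    litterfall_mult with all 12 months present for ``year``.  Temperature
    is additive-exact; moisture is additive then clipped to [0, 1];
    litterfall is scaled.  A zero anomaly is the identity.
    """
    sub = anomaly[anomaly["year"] == year]
    if sorted(sub["month"]) != list(range(1, 13)):
        raise ValueError(f"anomaly table must have months 1-12 for year {year}")
    by_month = sub.set_index("month")
    d_temp = by_month["d_temp"].to_numpy()[_DAY_MONTH - 1]
    d_moist = by_month["d_moisture"].to_numpy()[_DAY_MONTH - 1]
    lf_mult = by_month["litterfall_mult"].to_numpy()[_DAY_MONTH - 1]
    return DailyForcing(
        site_id=daily.site_id,
        temp=daily.temp + d_temp,
        moisture=np.clip(daily.moisture + d_moist, 0.0, 1.0),
        litterfall=daily.litterfall * lf_mult,
    )


def future_forcing(
    daily: DailyForcing, anomaly: pd.DataFrame, years: tuple[int, ...] = (2072, 2073, 2074)
) -> tuple[DailyForcing, SiteForcing | None]:
    """Mean anomaly-adjusted climatology over the future window.

    The historical climatology is cycled through each anomaly year and the
    adjusted years are averaged back into a single 365-day climatology, so
    the same steady-state + litterbag machinery runs unchanged.
    """
    adjusted = [apply_anomalies(daily, anomaly, y) for y in years]
    return DailyForcing(
        site_id=daily.site_id,
        temp=np.mean([a.temp for a in adjusted], axis=0),
        moisture=np.mean([a.moisture for a in adjusted], axis=0),
        litterfall=np.mean([a.litterfall for a in adjusted], axis=0),
    )


def _future_site(site: SiteForcing, fut: DailyForcing) -> SiteForcing:
    """Site statistics consistent with the future climatology."""
    return SiteForcing(
        site_id=site.site_id,
        litterfall=float(fut.litterfall.sum()),
        soil_t_mean=float(fut.temp.mean()),
        soil_t_sd=float(fut.temp.std()),
        moisture_mean=float(np.clip(fut.moisture.mean(), 0.0, 1.0)),
        moisture_sd=float(fut.moisture.std()),
        mult_min=site.mult_min,
        mult_max=site.mult_max,
        clay=site.clay,
        lignin_n=site.lignin_n,
        role=site.role,
    )


def _design_table(sites, daily, params, mult_sets, label):
    """Mass loss per run x timepoint; calibrated runs averaged over sets."""
    if mult_sets is None:
        table = run_design(sites, daily, params)
        table["model"] = label
        return table
    parts = []
    for ms in mult_sets:
        part = run_design(sites, daily, params, mults=ms)
        part["set_id"] = ms.draw_id
        parts.append(part)
    keys = ["site", "litter_id", "lignin_n", "moisture_variant", "timepoint"]
    table = (
        pd.concat(parts)
        .groupby(keys, as_index=False)
        .agg({"mass_loss_pct": "mean", "moisture": "first", "co_ratio": "mean"})
    )
    table["model"] = label
    return table


def climate_response(
    sites: list[SiteForcing],
    daily_forcings: dict[str, DailyForcing],
    anomaly: pd.DataFrame,
    params: KineticParameters,
    calibrated_sets: list[CalibrationMultiplierSet],
    *,
    years: tuple[int, ...] = (2072, 2073, 2074),
) -> pd.DataFrame:
    """Per-run climate responses of default and calibrated models.

    Returns one row per site x litter x moisture variant x timepoint with
    historical and future mass loss and the response delta for both
    parameterizations, the calibrated-vs-default percent difference (or
    absolute difference where the default response is within the guard),
    and the covariates the driver analysis uses.
    """
    fut_daily, fut_sites = {}, []
    for site in sites:
        fd = future_forcing(daily_forcings[site.site_id], anomaly, years)
        fut_daily[site.site_id] = fd
        fut_sites.append(_future_site(site, fd))

    keys = ["site", "litter_id", "moisture_variant", "timepoint"]
    frames = {}
    for label, s, d, msets in (
        ("default_hist", sites, daily_forcings, None),
        ("default_fut", fut_sites, fut_daily, None),
        ("cal_hist", sites, daily_forcings, calibrated_sets),
        ("cal_fut", fut_sites, fut_daily, calibrated_sets),
    ):
        frames[label] = _design_table(s, d, params, msets, label).set_index(keys)

    base = frames["default_hist"]
    out = pd.DataFrame(index=base.index).reset_index()
    out["lignin_n"] = base["lignin_n"].to_numpy()
    for label in frames:
        out[f"mass_loss_{label}"] = frames[label]["mass_loss_pct"].reindex(base.index).to_numpy()
    out["delta_default"] = out["mass_loss_default_fut"] - out["mass_loss_default_hist"]
    out["delta_calibrated"] = out["mass_loss_cal_fut"] - out["mass_loss_cal_hist"]

    diff = out["delta_calibrated"] - out["delta_default"]
    guard = out["delta_default"].abs() < PERCENT_DIFF_GUARD
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * diff / out["delta_default"].abs()
    out["cal_vs_default_pct"] = np.where(guard, diff, pct)
    out["pct_is_absolute"] = guard

    site_map = {s.site_id: s for s in sites}
    fut_map = {s.site_id: s for s in fut_sites}
    out["clay"] = [site_map[s].clay for s in out["site"]]
    out["moisture_variability"] = [
        site_map[s].mult_max - site_map[s].mult_min for s in out["site"]
    ]
    for tag, smap in (("hist", site_map), ("fut", fut_map)):
        out[f"litterfall_{tag}"] = [smap[s].litterfall for s in out["site"]]
        out[f"soil_t_{tag}"] = [smap[s].soil_t_mean for s in out["site"]]
        out[f"moisture_{tag}"] = [
            smap[s].moisture_scalar(v) for s, v in zip(out["site"], out["moisture_variant"])
        ]
    return out


def driver_analysis(response: pd.DataFrame) -> dict[str, pd.Series]:
    """Mixed-model drivers of the calibrated-vs-default climate response.

    Fits the 126-row response table (7 sites x 2 timepoints x 3 litters x
    3 moisture variants) with plot-within-site random intercepts in three
    covariate variants: historical levels, future levels, and deltas
    (future minus historical) of litterfall, soil temperature and soil
    moisture, always alongside site clay, site moisture variability and
    plot lignin:N.  Moisture levels are log transformed; deltas are not.
    Returns fixed-effect coefficients per variant.
    """
    table = response.copy()
    table["plot"] = (
        table["site"] + "-" + table["litter_id"].astype(str) + "-" + table["moisture_variant"]
    )
    cols6 = ["clay", "moisture_variability", "lignin_n", "x_litterfall", "x_soil_t", "x_moisture"]
    if float(np.std(table["cal_vs_default_pct"])) < 1e-12:
        # degenerate response (e.g. identical parameterizations): the mixed
        # model is unidentified and every effect is exactly zero
        flat = pd.Series(0.0, index=cols6)
        return {variant: flat.copy() for variant in ("hist", "fut", "delta")}
    out = {}
    for variant in ("hist", "fut", "delta"):
        df = table.copy()
        if variant == "delta":
            df["x_litterfall"] = df["litterfall_fut"] - df["litterfall_hist"]
            df["x_soil_t"] = df["soil_t_fut"] - df["soil_t_hist"]
            df["x_moisture"] = df["moisture_fut"] - df["moisture_hist"]
        else:
            df["x_litterfall"] = df[f"litterfall_{variant}"]
            df["x_soil_t"] = df[f"soil_t_{variant}"]
            df["x_moisture"] = np.log(np.maximum(df[f"moisture_{variant}"], 1e-6))
        cols = ["clay", "moisture_variability", "lignin_n", "x_litterfall", "x_soil_t", "x_moisture"]
        for col in cols:
            x = df[col].to_numpy(dtype=float)
            sd = x.std()
            df[col] = (x - x.mean()) / sd if sd > 0 else 0.0
        formula = "cal_vs_default_pct ~ " + " + ".join(cols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                formula,
                data=df,
                groups="site",
                re_formula="1",
                vc_formula={"plot": "0 + C(plot)"},
            )
            try:
                fit = model.fit(reml=True, method=["powell", "lbfgs"], maxiter=2000)
            except Exception:
                model = sm.MixedLM.from_formula(formula, data=df, groups="site", re_formula="1")
                fit = model.fit(reml=True, method=["powell", "lbfgs"], maxiter=2000)
        out[variant] = pd.Series(fit.fe_params).drop("Intercept")
    return out
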