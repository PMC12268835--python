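"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline can run without external downloads: this module
generates (a) daily forcing climatologies consistent with the site-table
annual means and standard deviations, (b) plot-level field observations with
the stated effect structure (soil moisture positive, lignin:N negative,
copiotroph:oligotroph negative), (c) taxonomy-labelled ASV count tables with
known group composition, (d) monthly SSP-style climate anomalies, and
(e) self-consistent "observed" mass-loss tables produced by running the
model itself under a reference multiplier set plus seeded noise (used for
closed-loop calibration).

All generators are deterministic under a fixed seed and emit their
generating truth where recovery tests need it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .forcing import DailyForcing, SiteForcing
from .params import CalibrationMultiplierSet, KineticParameters

__all__ = [
    "generate_daily_forcing",
    "compute_moisture_multipliers",
    "ObservationGeneratorConfig",
    "generate_observations",
    "generate_asv_table",
    "generate_anomalies",
    "generate_model_observations",
]

# Plot counts per calibration site in the default observational design
# (totalling 62 plots, i.e. 124 rows over two timepoints).
DEFAULT_PLOTS_PER_SITE = {
    "TREE": 10, "BART": 8, "HARV": 5, "GRSM": 5, "SERC": 12, "TALL": 11, "LENO": 11,
}


def generate_daily_forcing(site: SiteForcing, seed: int) -> DailyForcing:
    """A 365-day climatology: seasonal sinusoid plus seeded noise.

    The temperature and moisture series are rescaled so their annual mean
    and standard deviation match the site statistics exactly (moisture is
    then clipped to [0, 1], which perturbs the match only marginally for
    wet sites).  Daily litterfall is an autumn-peaked pulse over a small
    uniform baseline, normalised to the annual total.
    """
    rng = np.random.default_rng(seed)
    days = np.arange(365)

    def seasonal(mean, sd, peak_day):
        wave = np.cos(2.0 * np.pi * (days - peak_day) / 365.0)
        noise = rng.normal(0.0, 0.3, size=365)
        # smooth the noise a little so days are autocorrelated
        kernel = np.ones(7) / 7.0
        noise = np.convolve(np.concatenate([noise[-6:], noise]), kernel, mode="valid")
        series = wave + noise
        series = (series - series.mean()) / series.std()
        return mean + sd * series

    temp = seasonal(site.soil_t_mean, site.soil_t_sd, peak_day=200)
    moisture = np.clip(seasonal(site.moisture_mean, site.moisture_sd, peak_day=100), 0.0, 1.0)

    pulse = np.exp(-0.5 * ((days - 289) / 15.0) ** 2)
    litterfall = 0.1 + pulse
    litterfall *= site.litterfall / litterfall.sum()

    return DailyForcing(site_id=site.site_id, temp=temp, moisture=moisture, litterfall=litterfall)


def compute_moisture_multipliers(samples: np.ndarray) -> tuple[float, float]:
    """Min/max moisture multipliers from field samples: the lower and upper
    95% confidence limits of the mean, divided by the mean."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("sample mean must be positive")
    sem = x.std(ddof=1) / np.sqrt(x.size)
    tcrit = stats.t.ppf(0.975, df=x.size - 1)
    return float((mean - tcrit * sem) / mean), float((mean + tcrit * sem) / mean)


@dataclasses.dataclass
class ObservationGeneratorConfig:
    """Generating model for synthetic plot-level field observations.

    Fixed-effect coefficients are on the standardized-predictor scale
    (percentage points of mass loss per SD); their signs encode the
    empirical effect structure.
    """

    b_moisture: float = 5.0
    b_lignin_n: float = -3.0
    b_co: float = -4.0
    intercept_t1: float = 32.0
    intercept_t2: float = 58.0
    site_sd: float = 3.0
    plot_sd: float = 2.0
    residual_sd: float = 4.0
    plots_per_site: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.b_moisture <= 0 or self.b_lignin_n >= 0 or self.b_co >= 0:
            raise ValueError(
                "effect signs must be moisture > 0, lignin:N < 0, copiotroph:oligotroph < 0"
            )
        for name in ("site_sd", "plot_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_observations(
    sites: list[SiteForcing],
    cfg: ObservationGeneratorConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic field observation table plus the generating truth.

    One row per plot x timepoint.  Plot covariates: log-normal soil
    moisture anchored at the site mean, lignin:N drawn near one of the
    site's three litter values, log-normal copiotroph:oligotroph ratio.
    Mass loss is the linear mixed model applied to the standardized
    covariates plus site, plot and residual noise, clipped to [0, 100].
    """
    cfg = cfg or ObservationGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    plots_per_site = cfg.plots_per_site or {
        s.site_id: DEFAULT_PLOTS_PER_SITE.get(s.site_id, 9) for s in sites
    }

    rows = []
    for site in sites:
        n_plots = plots_per_site[site.site_id]
        site_eff = rng.normal(0.0, cfg.site_sd)
        for plot in range(n_plots):
            moisture = float(
                np.exp(rng.normal(np.log(max(site.moisture_mean, 1e-3)), 0.25))
            )
            lignin_n = float(
                rng.choice(site.lignin_n) * np.exp(rng.normal(0.0, 0.08))
            )
            co_ratio = float(np.exp(rng.normal(0.0, 0.5)))
            plot_eff = rng.normal(0.0, cfg.plot_sd)
            for tp, intercept in ((10, cfg.intercept_t1), (21, cfg.intercept_t2)):
                rows.append(
                    {
                        "site": site.site_id,
                        "plot": f"{site.site_id}-{plot:02d}",
                        "timepoint": tp,
                        "moisture": moisture,
                        "lignin_n": lignin_n,
                        "co_ratio": co_ratio,
                        "site_eff": site_eff,
                        "plot_eff": plot_eff,
                        "intercept": intercept,
                    }
                )
    table = pd.DataFrame(rows)

    def z(series):
        x = np.asarray(series, dtype=float)
        return (x - x.mean()) / x.std(ddof=0)

    lin = (
        table["intercept"]
        + cfg.b_moisture * z(np.log(table["moisture"]))
        + cfg.b_lignin_n * z(table["lignin_n"])
        + cfg.b_co * z(table["co_ratio"])
        + table["site_eff"]
        + table["plot_eff"]
        + rng.normal(0.0, cfg.residual_sd, size=len(table))
    )
    table["mass_loss_pct"] = np.clip(lin, 0.0, 100.0)
    table = table.drop(columns=["site_eff", "plot_eff", "intercept"])
    truth = {
        "b_moisture": cfg.b_moisture,
        "b_lignin_n": cfg.b_lignin_n,
        "b_co": cfg.b_co,
        "seed": cfg.seed,
    }
    return table, truth


def generate_asv_table(
    n_samples: int = 12,
    n_taxa: int = 60,
    group_proportions: dict[str, float] | None = None,
    mean_depth: float = 6000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Taxonomy-labelled ASV counts with known group composition.

    Returns ``(table, rules, truth)``: a taxa x samples count table with a
    lineage column, the matching classification rule table, and the true
    copiotroph:oligotroph proportion ratio per sample.
    """
    props = group_proportions or {"copiotroph": 0.4, "oligotroph": 0.4, "unassigned": 0.2}
    if sum(props.values()) > 1.0 + 1e-9:
        raise ValueError("group proportions must sum to at most 1")
    rng = np.random.default_rng(seed)

    groups = rng.choice(
        list(props), size=n_taxa, p=np.array(list(props.values())) / sum(props.values())
    )
    phyla = {
        "copiotroph": "Copiophyla",
        "oligotroph": "Oligophyla",
        "unassigned": "Incertae",
    }
    lineages, rules = [], {("phylum", "Copiophyla"): "copiotroph",
                           ("phylum", "Oligophyla"): "oligotroph"}
    for i, g in enumerate(groups):
        lineages.append(f"phylum:{phyla[g]};genus:Taxon{i:03d}")

    base = rng.dirichlet(np.ones(n_taxa) * 0.8)
    counts = np.zeros((n_taxa, n_samples), dtype=int)
    depths = np.maximum(rng.poisson(mean_depth, size=n_samples), 1)
    for j in range(n_samples):
        p = rng.dirichlet(base * 400.0)
        counts[:, j] = rng.multinomial(depths[j], p)

    table = pd.DataFrame(counts, columns=[f"S{j:02d}" for j in range(n_samples)])
    table.insert(0, "lineage", lineages)
    table.insert(0, "taxon_id", [f"ASV{i:04d}" for i in range(n_taxa)])

    rule_df = pd.DataFrame(
        [{"rank": r, "name": n, "group": g} for (r, n), g in rules.items()]
    )
    copio = counts[groups == "copiotroph"].sum(axis=0)
    oligo = counts[groups == "oligotroph"].sum(axis=0)
    with np.errstate(divide="ignore"):
        truth = pd.Series(copio / np.where(oligo > 0, oligo, np.nan), index=table.columns[2:])
    return table, rule_df, truth


def generate_anomalies(
    years: tuple[int, ...] = (2072, 2073, 2074),
    *,
    baseline_year: int = 2022,
    d_temp_mean: float = 3.0,
    d_temp_seasonal: float = 1.0,
    d_moisture_mean: float = -0.03,
    litterfall_change: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Monthly SSP-style anomalies ramping linearly from the baseline year.

    Warming is stronger in winter months (a month-dependent shape on top of
    the mean delta); moisture anomalies are additive on the 0-1 scalar and
    drier in summer; litterfall changes multiplicatively.
    """
    rng = np.random.default_rng(seed)
    end_year = max(years)
    rows = []
    for year in years:
        ramp = (year - baseline_year) / (end_year - baseline_year)
        for month in range(1, 13):
            season = np.cos(2.0 * np.pi * (month - 1) / 12.0)  # peak in January
            d_t = ramp * (d_temp_mean + d_temp_seasonal * season) + rng.normal(0, 0.05)
            d_m = ramp * (d_moisture_mean - 0.01 * season) + rng.normal(0, 0.002)
            lf = 1.0 + ramp * litterfall_change
            rows.append(
                {
                    "year": year,
                    "month": month,
                    "d_temp": d_t,
                    "d_moisture": d_m,
                    "litterfall_mult": lf,
                }
            )
    return pd.DataFrame(rows)


def generate_model_observations(
    sites: list[SiteForcing],
    daily_forcings: dict[str, DailyForcing],
    params: KineticParameters,
    truth_mults: CalibrationMultiplierSet,
    *,
    seed: int = 0,
    noise_sd: float = 1.5,
    co_noise_sd: float = 0.10,
):
    """Self-consistent synthetic "observations" from a known multiplier set.

    Runs the full litterbag design under ``truth_mults``, perturbs each
    run x timepoint mass loss with seeded Gaussian noise (percentage
    points), and returns ``(obs_table, envelope, truth_mults)``.  The
    envelope holds per-site min/mean/max mass loss per timepoint across the
    nine within-site runs, mirroring how field plots bound site-level
    variation.  ``obs_table`` is a plot-level table (plot = litter x
    moisture combination) suitable for the effect-size stage, with the
    steady-state copiotroph:oligotroph ratio perturbed by log-normal noise.
    """
    from .litterbag import run_design  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    table = run_design(sites, daily_forcings, params, mults=truth_mults)
    table = table.copy()
    table["mass_loss_pct"] = np.clip(
        table["mass_loss_pct"] + rng.normal(0.0, noise_sd, size=len(table)), 0.0, 100.0
    )
    table["co_ratio"] = np.minimum(table["co_ratio"], 1e3) * np.exp(
        rng.normal(0.0, co_noise_sd, size=len(table))
    )
    table["plot"] = (
        table["site"] + "-" + table["litter_id"].astype(str) + "-" + table["moisture_variant"]
    )
    envelope = (
        table.groupby(["site", "timepoint"])["mass_loss_pct"]
        .agg(obs_min="min", obs_mean="mean", obs_max="max")
        .reset_index()
    )
    return table, envelope, truth_mults
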