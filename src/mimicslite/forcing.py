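"""Site forcing: annual statistics and daily climatologies.

A :class:`SiteForcing` carries the annual-mean statistics used to solve model
steady states (litterfall, soil temperature, the 0-1 soil-moisture scalar,
clay, and three litter lignin:N values per site).  A :class:`DailyForcing`
is a 365-day climatology of temperature, moisture scalar, and litter input
used to drive litterbag simulations; it is cycled across calendar years.

A table of ten temperate-forest sites (seven calibration, three validation)
ships with the package and is the default experimental design.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SiteForcing",
    "DailyForcing",
    "load_site_table",
    "site_from_row",
    "load_sites",
    "MOISTURE_VARIANTS",
]

MOISTURE_VARIANTS = ("min", "mean", "max")


@dataclasses.dataclass(frozen=True)
class SiteForcing:
    """Annual forcing statistics for one site."""

    site_id: str
    litterfall: float  # gC m-2 yr-1
    soil_t_mean: float  # degC
    soil_t_sd: float
    moisture_mean: float  # unitless 0-1 scalar
    moisture_sd: float
    mult_min: float
    mult_max: float
    clay: float  # fraction 0-1
    lignin_n: tuple[float, float, float]
    role: str = "calibration"

    def __post_init__(self):
        if not 0.0 <= self.moisture_mean <= 1.0:
            raise ValueError(f"moisture_mean must lie in [0, 1], got {self.moisture_mean}")
        if not self.mult_min <= 1.0 <= self.mult_max:
            raise ValueError("moisture multipliers must bracket 1")
        if not 0.0 <= self.clay <= 1.0:
            raise ValueError(f"clay must be a fraction in [0, 1], got {self.clay}")
        if any(v <= 0 for v in self.lignin_n):
            raise ValueError("lignin:N values must be positive")

    def moisture_multiplier(self, variant: str) -> float:
        try:
            return {"min": self.mult_min, "mean": 1.0, "max": self.mult_max}[variant]
        except KeyError:
            raise ValueError(f"unknown moisture variant {variant!r}") from None

    def moisture_scalar(self, variant: str) -> float:
        """Annual-mean moisture scalar for a variant, clipped to [0, 1]."""
        return float(np.clip(self.moisture_mean * self.moisture_multiplier(variant), 0.0, 1.0))


@dataclasses.dataclass
class DailyForcing:
    """A 365-day climatology driving litterbag simulations."""

    site_id: str
    temp: np.ndarray  # degC, shape (365,)
    moisture: np.ndarray  # 0-1 scalar, shape (365,)
    litterfall: np.ndarray  # gC m-2 day-1, shape (365,)

    def __post_init__(self):
        for name in ("temp", "moisture", "litterfall"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (365,):
                raise ValueError(f"{name} must have shape (365,), got {arr.shape}")
            setattr(self, name, arr)
        if self.moisture.min() < 0 or self.moisture.max() > 1:
            raise ValueError("moisture scalar must lie in [0, 1]")

    @property
    def annual_litterfall(self) -> float:
        return float(self.litterfall.sum())


def load_site_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read the site table (packaged fixture by default)."""
    if path is None:
        with resources.files("mimicslite.data").joinpath("site_table.csv").open("r") as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def site_from_row(row: pd.Series) -> SiteForcing:
    return SiteForcing(
        site_id=str(row["site_id"]),
        litterfall=float(row["litterfall"]),
        soil_t_mean=float(row["soil_t_mean"]),
        soil_t_sd=float(row["soil_t_sd"]),
        moisture_mean=float(row["moisture_mean"]),
        moisture_sd=float(row["moisture_sd"]),
        mult_min=float(row["mult_min"]),
        mult_max=float(row["mult_max"]),
        clay=float(row["clay_pct"]) / 100.0,
        lignin_n=(
            float(row["lignin_n_1"]),
            float(row["lignin_n_2"]),
            float(row["lignin_n_3"]),
        ),
        role=str(row.get("role", "calibration")),
    )


def load_sites(path: str | Path | None = None, role: str | None = None) -> list[SiteForcing]:
    """Load sites, optionally restricted to ``calibration`` or ``validation``."""
    table = load_site_table(path)
    if role is not None:
        table = table[table["role"] == role]
        if table.empty:
            raise ValueError(f"no sites with role {role!r} in site table")
    return [site_from_row(row) for _, row in table.iterrows()]
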