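"""Model parameters, calibration multipliers, and their validation.

The seven-pool model is driven by a single :class:`KineticParameters` object
holding every rate, efficiency, partitioning and turnover constant.  Defaults
live in the packaged ``data/default_params.yaml`` file; any subset can be
overridden from a user YAML file, so an alternative published configuration
can be dropped in verbatim without touching code.

Four of these parameters are calibratable through dimensionless multipliers
(:class:`CalibrationMultiplierSet`): the litter-quality coefficient on
copiotrophic turnover, the density-dependence exponent ``beta``, and the
metabolic and structural Vmax modifiers (applied to both microbial groups).
"""

from __future__ import annotations

import copy as _copy
import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "KineticParameters",
    "CalibrationMultiplierSet",
    "MULTIPLIER_RANGES",
    "default_parameters",
    "load_parameters",
    "apply_multipliers",
    "load_calibrated_sets",
    "MICROBES",
    "SUBSTRATES",
]

MICROBES = ("r", "k")  # copiotrophic, oligotrophic
SUBSTRATES = ("m", "s", "a")  # metabolic litter, structural litter, available SOM

#: Sampling ranges for the four calibration multipliers.
MULTIPLIER_RANGES: dict[str, tuple[float, float]] = {
    "m_tau_r": (0.3, 2.0),
    "m_beta": (0.67, 1.33),
    "m_vmod_m": (0.5, 2.0),
    "m_vmod_s": (0.5, 2.0),
}


@dataclasses.dataclass
class KineticParameters:
    """All kinetic and stoichiometric constants of the seven-pool model.

    Units: pools mgC cm^-3, time hours, temperature degC.  See the packaged
    ``default_params.yaml`` for field-by-field documentation.
    """

    depth_cm: float
    vmax_scale: float
    v_slope: float
    v_int: float
    a_v: float
    v_mod_m: dict[str, float]
    v_mod_s: dict[str, float]
    v_mod_a: dict[str, float]
    k_slope: dict[str, float]
    k_int: float
    a_k: float
    k_mod_m: dict[str, float]
    k_mod_s: dict[str, float]
    k_mod_a: dict[str, float]
    k_o: dict[str, float]
    cue: dict[str, float]
    tau_base: dict[str, float]
    tau_mod_r: float
    tau_mod_k: float
    beta: float
    f_s: dict[str, dict[str, float]]
    f_i: dict[str, float]
    d_base: float
    d_clay: float
    f_met0: float
    f_met_slope: float
    moisture_on_som: bool = True
    bag_c0: float = 1.25

    def validate(self) -> None:
        """Raise ``ValueError`` on any physically inadmissible setting."""
        positive = {
            "depth_cm": self.depth_cm,
            "vmax_scale": self.vmax_scale,
            "a_v": self.a_v,
            "a_k": self.a_k,
            "beta": self.beta,
            "d_base": self.d_base,
            "f_met0": self.f_met0,
            "f_met_slope": self.f_met_slope,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for microbe in MICROBES:
            for group in (self.v_mod_m, self.v_mod_s, self.v_mod_a,
                          self.k_mod_m, self.k_mod_s, self.k_mod_a,
                          self.k_o, self.tau_base):
                if not group[microbe] > 0:
                    raise ValueError(f"rate modifier for microbe {microbe!r} must be > 0")
            fs = self.f_s[microbe]
            total = fs["som_p"] + fs["som_c"] + fs["som_a"]
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"turnover partition fractions for microbe {microbe!r} sum to "
                    f"{total}, expected 1"
                )
        for key, value in self.cue.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"cue[{key}] must lie in (0, 1), got {value}")
        for key, value in self.f_i.items():
            if not 0.0 <= value < 1.0:
                raise ValueError(f"f_i[{key}] must lie in [0, 1), got {value}")

    def copy(self) -> "KineticParameters":
        return _copy.deepcopy(self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "KineticParameters":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        params = cls(**{k: _copy.deepcopy(v) for k, v in data.items()})
        params.validate()
        return params


def _packaged(name: str):
    return resources.files("mimicslite.data").joinpath(name)


def default_parameters() -> KineticParameters:
    """The packaged default configuration (Vmax globally scaled by 0.6)."""
    with _packaged("default_params.yaml").open("r") as fh:
        data = yaml.safe_load(fh)
    return KineticParameters.from_dict(data)


def load_parameters(path: str | Path) -> KineticParameters:
    """Load a parameter file; missing keys fall back to packaged defaults."""
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    base = default_parameters().to_dict()
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            base[key].update(value)
        else:
            base[key] = value
    return KineticParameters.from_dict(base)


@dataclasses.dataclass(frozen=True)
class CalibrationMultiplierSet:
    """One draw of the four calibration multipliers."""

    m_tau_r: float
    m_beta: float
    m_vmod_m: float
    m_vmod_s: float
    draw_id: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "m_tau_r": self.m_tau_r,
            "m_beta": self.m_beta,
            "m_vmod_m": self.m_vmod_m,
            "m_vmod_s": self.m_vmod_s,
        }

    def validate(self, ranges: Mapping[str, tuple[float, float]] = MULTIPLIER_RANGES) -> None:
        for name, value in self.as_dict().items():
            lo, hi = ranges[name]
            if not lo <= value <= hi:
                raise ValueError(
                    f"multiplier {name}={value} outside allowed range [{lo}, {hi}]"
                )

    @classmethod
    def identity(cls) -> "CalibrationMultiplierSet":
        return cls(1.0, 1.0, 1.0, 1.0)


def apply_multipliers(
    defaults: KineticParameters,
    mults: CalibrationMultiplierSet,
    *,
    check_ranges: bool = True,
) -> KineticParameters:
    """Scale the four calibratable parameters; everything else is untouched.

    ``m_vmod_m`` and ``m_vmod_s`` scale the metabolic and structural Vmax
    modifiers of *both* microbial groups with the same factor.
    """
    if check_ranges:
        mults.validate()
    out = defaults.copy()
    out.tau_mod_r = defaults.tau_mod_r * mults.m_tau_r
    out.beta = defaults.beta * mults.m_beta
    for microbe in MICROBES:
        out.v_mod_m[microbe] = defaults.v_mod_m[microbe] * mults.m_vmod_m
        out.v_mod_s[microbe] = defaults.v_mod_s[microbe] * mults.m_vmod_s
    return out


def load_calibrated_sets() -> list[CalibrationMultiplierSet]:
    """The three calibrated multiplier sets shipped as a packaged fixture."""
    with _packaged("calibrated_sets.csv").open("r") as fh:
        table = pd.read_csv(fh)
    return [
        CalibrationMultiplierSet(
            m_tau_r=row.m_tau_r,
            m_beta=row.m_beta,
            m_vmod_m=row.m_vmod_m,
            m_vmod_s=row.m_vmod_s,
            draw_id=int(row.set_id),
        )
        for row in table.itertuples()
    ]
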