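"""Chamber and species configuration.

The flux inversion needs a handful of physical constants: the chamber volume
and leak rate, ambient CO2, measurement temperature/pressure, a per-species
Michaelis–Menten half-saturation constant (Km) for ethylene production as a
function of acetylene, and a per-species mol-ethylene : mol-N conversion
factor.  The leak rate keff and Km are published as a mean with a 95% CI but
enter the parametric bootstrap as gamma distributions, so the gamma
shape/rate is recovered here by quantile matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize, stats

GAS_CONSTANT = 8.31446261815324  # J mol-1 K-1

SYMBIOSIS_TYPES = ("rhizobial", "actinorhizal")
BIOMES = ("temperate", "tropical")


class ConfigError(ValueError):
    """Invalid chamber/species configuration."""


def gamma_from_mean_ci(
    mean: float, ci_low: float, ci_high: float, *, rel_tol: float = 0.25
) -> tuple[float, float]:
    """Gamma (shape, rate) matching a mean exactly and a 95% CI approximately.

    The rate is pinned at shape/mean so the mean is exact; the shape is found
    by minimising the squared relative error of the (2.5%, 97.5%) quantiles
    against ``(ci_low, ci_high)``.

    Parameters
    ----------
    mean, ci_low, ci_high
        Published mean and 95% CI bounds, all positive, ``ci_low < mean < ci_high``.
    rel_tol
        Maximum acceptable relative error of either matched quantile.

    Returns
    -------
    (shape, rate)
    """
    if not (0.0 < ci_low < mean < ci_high):
        raise ConfigError(
            f"need 0 < ci_low < mean < ci_high, got ({ci_low}, {mean}, {ci_high})"
        )
    target = np.array([ci_low, ci_high])

    def loss(log_shape: float) -> float:
        shape = float(np.exp(log_shape))
        q = stats.gamma.ppf([0.025, 0.975], a=shape, scale=mean / shape)
        return float(np.sum(((q - target) / target) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-3), np.log(1e9)), method="bounded")
    shape = float(np.exp(res.x))
    rate = shape / mean
    q = stats.gamma.ppf([0.025, 0.975], a=shape, scale=1.0 / rate)
    rel_err = np.abs(q - target) / target
    if not res.success or np.any(rel_err > rel_tol):
        raise ConfigError(
            "no gamma matches the stated CI: "
            f"best shape {shape:.4g} gives quantiles {q} for target {target} "
            f"(relative errors {rel_err})"
        )
    return shape, rate


@dataclass(frozen=True)
class ChamberConfig:
    """Physical constants of one incubation-chamber setup.

    ``keff`` is the first-order leak rate constant (h^-1) shared by ethylene,
    acetylene and CO2; its gamma parameterisation is derived from the
    published mean + 95% CI at construction.
    """

    volume_liters: float = 40.5
    keff_mean: float = 0.0045
    keff_ci: tuple[float, float] = (0.0010, 0.0105)
    ambient_co2: float = 400.0
    temperature: float = 25.0  # degrees C during the measurement
    pressure: float = 101.325  # kPa
    a0_rel_sd: float = 0.02  # relative SD of the starting acetylene concentration
    keff_gamma: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.volume_liters <= 0:
            raise ConfigError("chamber volume must be positive")
        if self.keff_mean <= 0:
            raise ConfigError("keff_mean must be positive")
        lo, hi = self.keff_ci
        if not (lo < self.keff_mean < hi):
            raise ConfigError("keff CI must bracket the mean")
        if self.ambient_co2 <= 0:
            raise ConfigError("ambient CO2 must be positive")
        shape, rate = gamma_from_mean_ci(self.keff_mean, lo, hi)
        if abs(shape / rate - self.keff_mean) > 1e-6 * self.keff_mean:
            raise ConfigError("derived gamma mean does not match keff_mean")
        object.__setattr__(self, "keff_gamma", (shape, rate))

    @property
    def molar_content(self) -> float:
        """Total moles of air in the chamber, n = P V / (R T)."""
        p_pa = self.pressure * 1e3
        v_m3 = self.volume_liters * 1e-3
        t_k = self.temperature + 273.15
        return p_pa * v_m3 / (GAS_CONSTANT * t_k)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species assay constants.

    ``km`` is the half-saturation acetylene concentration (ppm) for ethylene
    production; ``conversion_factor`` is mol ethylene produced per mol N fixed,
    used to convert nitrogenase activity to SNF.
    """

    species: str
    km: float
    km_ci: tuple[float, float]
    conversion_factor: float
    symbiosis: str
    biome: str
    km_gamma: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ConfigError("km must be positive")
        if self.conversion_factor <= 0:
            raise ConfigError("conversion factor must be positive")
        if self.symbiosis not in SYMBIOSIS_TYPES:
            raise ConfigError(f"symbiosis must be one of {SYMBIOSIS_TYPES}")
        if self.biome not in BIOMES:
            raise ConfigError(f"biome must be one of {BIOMES}")
        object.__setattr__(self, "km_gamma", gamma_from_mean_ci(self.km, *self.km_ci))


@dataclass(frozen=True)
class BootstrapConfig:
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigError("n_draws must be >= 1")


@dataclass(frozen=True)
class PipelineConfig:
    chamber: ChamberConfig
    species: dict[str, SpeciesParams]
    bootstrap: BootstrapConfig


def load_config(path) -> PipelineConfig:
    """Read the YAML config (blocks: chamber, species, bootstrap)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "chamber" not in raw:
        raise ConfigError("config must be a mapping with a 'chamber' block")
    ch = raw["chamber"]
    chamber = ChamberConfig(
        volume_liters=float(ch.get("volume_liters", 40.5)),
        keff_mean=float(ch.get("keff_mean", 0.0045)),
        keff_ci=tuple(float(x) for x in ch.get("keff_ci", (0.0010, 0.0105))),
        ambient_co2=float(ch.get("ambient_co2_ppm", 400.0)),
        temperature=float(ch.get("temperature_c", 25.0)),
        pressure=float(ch.get("pressure_kpa", 101.325)),
        a0_rel_sd=float(ch.get("a0_rel_sd", 0.02)),
    )
    species: dict[str, SpeciesParams] = {}
    for name, sp in (raw.get("species") or {}).items():
        species[name] = SpeciesParams(
            species=name,
            km=float(sp["km_ppm"]),
            km_ci=tuple(float(x) for x in sp["km_ci"]),
            conversion_factor=float(sp["conversion_factor"]),
            symbiosis=sp["symbiosis"],
            biome=sp["biome"],
        )
    bs = raw.get("bootstrap") or {}
    bootstrap = BootstrapConfig(
        n_draws=int(bs.get("n_draws", 10_000)), seed=int(bs.get("seed", 0))
    )
    return PipelineConfig(chamber=chamber, species=species, bootstrap=bootstrap)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Round-trippable plain-dict form of a config (for manifests/logging)."""
    def clean(dc):
        d = dataclasses.asdict(dc)
        d.pop("keff_gamma", None)
        d.pop("km_gamma", None)
        return d

    return {
        "chamber": clean(cfg.chamber),
        "species": {k: clean(v) for k, v in cfg.species.items()},
        "bootstrap": dataclasses.asdict(cfg.bootstrap),
    }
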