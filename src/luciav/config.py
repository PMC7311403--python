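"""Default configuration and parameter builders.

The shipped ``data/default_config.yaml`` holds the default synthetic world:
climate-generator settings, the land-use schedule shape, initial land areas,
biome parameters and the climate-sensitivity calibration constants.  Values
are plain data so a study can copy and edit the file rather than the code.
"""

from __future__ import annotations

import math
from importlib import resources

import yaml

from .cohorts import ClassSens, RegionParams, SensitivityParams

__all__ = [
    "default_config",
    "load_config",
    "calibrated_growth_k",
    "biome_params",
    "make_region_params",
    "BIOME_AGES",
]

#: biome age thresholds (years) at which regrowing forest counts as intact
BIOME_AGES = {"tropical": 70.0, "temperate": 90.0, "boreal": 160.0}

_BIOME_DEFAULTS = {
    "tropical": {"b_max": 150.0, "f_burn": 0.5, "k_litter": 0.3},
    "temperate": {"b_max": 90.0, "f_burn": 0.4, "k_litter": 0.2},
    "boreal": {"b_max": 60.0, "f_burn": 0.4, "k_litter": 0.12},
}


def default_config() -> dict:
    """Load the packaged default configuration."""
    text = resources.files("luciav").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def calibrated_growth_k(intact_age: float, theta: float, threshold: float = 0.9) -> float:
    """Chapman–Richards rate so the curve crosses ``threshold * b_max`` at ``intact_age``."""
    if intact_age <= 0:
        raise ValueError("intact_age must be positive")
    return -math.log(1.0 - threshold ** (1.0 / theta)) / intact_age


def _sens_from(cfg: dict | None) -> SensitivityParams:
    cfg = cfg or {}
    return SensitivityParams(
        agri=ClassSens(**cfg.get("agri", {})),
        secondary=ClassSens(**cfg.get("secondary", {})),
        intact=ClassSens(**cfg.get("intact", {})),
    )


def biome_params(biome: str, sens: SensitivityParams | None = None, **overrides) -> RegionParams:
    """RegionParams with biome defaults and the regrowth rate calibrated so
    intact promotion lands near the biome age (70/90/160 yr)."""
    if biome not in BIOME_AGES:
        raise ValueError(f"unknown biome {biome!r}")
    kw = dict(_BIOME_DEFAULTS[biome])
    kw["biome"] = biome
    kw["intact_age"] = BIOME_AGES[biome]
    theta = overrides.get("growth_theta", 2.0)
    kw["growth_k"] = calibrated_growth_k(kw["intact_age"], theta)
    kw.update(overrides)
    if sens is not None:
        kw["sens"] = sens
    return RegionParams(**kw)


def make_region_params(cfg: dict) -> RegionParams:
    """Build RegionParams from a config mapping (``region`` + ``sens`` blocks)."""
    region = dict(cfg.get("region", {}))
    sens = _sens_from(cfg.get("sens"))
    biome = region.pop("biome", "tropical")
    return biome_params(biome, sens=sens, **region)
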