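"""Structured-text (YAML) configuration: site/soil, plant parameters,
generator statistics, scenarios, and packaged defaults.

The packaged defaults under ``dynagrass/data`` describe a synthetic
high-elevation pre-alpine site (864 m a.s.l., clay-rich Cambisol-like
profile, ~1350 mm annual precipitation): they are calibration fixtures of
this package, not measured survey values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .management import ManagementRules, StaticSchedule, TargetBiomassModel
from .plant import PlantParams
from .soil import ManureComposition, SoilHorizon, SoilProfile
from .weather import GeneratorStats, ScenarioSpec

__all__ = [
    "load_yaml",
    "load_soil_profile",
    "load_plant_params",
    "load_generator_stats",
    "load_scenario",
    "load_rules",
    "default_soil_profile",
    "default_plant_params",
    "default_generator_stats",
    "default_scenario",
    "default_manure",
]

_SOIL_FIELDS = {
    "upper_cm", "lower_cm", "bulk_density", "ph", "c_org", "n_org",
    "clay", "silt", "sand", "field_capacity", "wilting_point",
    "hydraulic_conductivity", "stone_fraction",
}


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def _soil_profile_from_dict(data: dict) -> SoilProfile:
    horizons = []
    for h in data["horizons"]:
        unknown = set(h) - _SOIL_FIELDS
        if unknown:
            raise ValueError(f"unknown soil horizon fields: {sorted(unknown)}")
        horizons.append(SoilHorizon(**h))
    return SoilProfile(horizons)


def load_soil_profile(path) -> SoilProfile:
    return _soil_profile_from_dict(load_yaml(path))


def load_plant_params(path) -> PlantParams:
    return PlantParams.from_mapping(load_yaml(path))


def load_generator_stats(path) -> GeneratorStats:
    return GeneratorStats.from_dict(load_yaml(path))


def _scenario_from_dict(data: dict) -> ScenarioSpec:
    anchors = {
        int(year): (entry.get("temp_delta", 0.0), entry.get("precip_factor", 1.0))
        for year, entry in data.get("anchors", {}).items()
    }
    co2 = {int(y): float(p) for y, p in data.get("co2_anchors", {}).items()}
    kwargs = {"label": data.get("label", "scenario"), "anchors": anchors}
    if co2:
        kwargs["co2_anchors"] = co2
    return ScenarioSpec(**kwargs)


def load_scenario(path) -> ScenarioSpec:
    return _scenario_from_dict(load_yaml(path))


def load_rules(path) -> ManagementRules:
    data = load_yaml(path)
    if "manure_after_cut_exclusions" in data:
        data["manure_after_cut_exclusions"] = frozenset(data["manure_after_cut_exclusions"])
    return ManagementRules(**data)


def _data_path(name: str) -> Path:
    return resources.files("dynagrass").joinpath("data", name)


def default_soil_profile() -> SoilProfile:
    return _soil_profile_from_dict(yaml.safe_load(_data_path("soil_prealpine.yaml").read_text()))


def default_plant_params() -> PlantParams:
    return PlantParams.from_mapping(yaml.safe_load(_data_path("plant_default.yaml").read_text()))


def default_generator_stats() -> GeneratorStats:
    return GeneratorStats.from_dict(yaml.safe_load(_data_path("weather_prealpine.yaml").read_text()))


def default_scenario(name: str = "baseline") -> ScenarioSpec:
    return _scenario_from_dict(yaml.safe_load(_data_path(f"scenario_{name}.yaml").read_text()))


def default_manure() -> ManureComposition:
    """Mean slurry characterization used for scheduled applications."""
    return ManureComposition()


def default_static_schedule() -> StaticSchedule:
    """Mean-calendar template: 4 cuts and 4 slurry applications per year at
    typical pre-alpine mean dates."""
    return StaticSchedule(cut_doys=(145, 190, 235, 280),
                          manure_doys=(105, 150, 195, 240),
                          composition=default_manure())


def default_target_model(altitude: float = 864.0) -> TargetBiomassModel:
    from .management import annual_yield_kg
    return TargetBiomassModel(mode="general", annual_agb=annual_yield_kg(altitude))
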