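"""Simulation orchestration: spin-up, daily loop with an hourly
photosynthesis/respiration sub-loop, management execution, scenario
ensembles and management-mode comparisons.

The daily loop couples the modules in a fixed order: snow partitioning,
soil temperature, season bookkeeping, phenology, hourly canopy carbon
fluxes, growth/allocation, senescence, mineralization and nitrogen
redistribution, the water balance, and finally the end-of-day management
decision.  Carbon, water and nitrogen balances are closed to machine
precision each day and the residuals are logged so tests can assert them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import config as cfg
from . import management as mgmt
from . import plant as pl
from . import soil as sl
from . import weather as wx

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "run_scenario_ensemble",
    "compare_managements",
]

MODES = ("static", "dynamic", "dynamic_reduced_n")


@dataclass
class SimulationConfig:
    """Everything one run needs.  Build with the defaults and override."""

    latitude: float = 47.57
    altitude: float = 864.0
    profile: sl.SoilProfile = None
    params: pl.PlantParams = None
    mode: str = "dynamic"
    rules: mgmt.ManagementRules = field(default_factory=mgmt.ManagementRules)
    target_model: mgmt.TargetBiomassModel = None
    static_schedule: mgmt.StaticSchedule = None
    composition: sl.ManureComposition = field(default_factory=sl.ManureComposition)
    scenario: wx.ScenarioSpec = None
    weather: Optional[pd.DataFrame] = None
    gen_stats: Optional[wx.GeneratorStats] = None
    seed: int = 1
    start_year: int = 2011
    years: int = 10
    spinup_years: int = 2
    root_depth_cm: float = 30.0
    mineralization_rate: float = 3.5e-4   # 1/d of the slow organic pool
    initial_n_mineral: float = 20.0       # kg N/ha
    initial_n_organic: float = 8000.0     # kg N/ha
    interception_capacity: float = 1.0    # mm/d
    melt_factor: float = 2.0              # mm/degC/d
    snow_insulation: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.years < 1:
            raise ValueError("horizon must cover at least 1 year")
        if self.profile is None:
            self.profile = cfg.default_soil_profile()
        if self.params is None:
            self.params = cfg.default_plant_params()
        if self.target_model is None:
            self.target_model = cfg.default_target_model(self.altitude)
        if self.scenario is None:
            self.scenario = cfg.default_scenario("baseline")
        if self.mode == "static" and self.static_schedule is None:
            self.static_schedule = cfg.default_static_schedule()
        if self.mode == "dynamic_reduced_n":
            policy = mgmt.configure_reduced_N(self.composition,
                                              self.rules.annual_n_cap or 170.0)
            self._reduced_policy = policy
            if self.rules.annual_n_cap is None:
                self.rules = dataclasses.replace(self.rules, annual_n_cap=policy.cap)
        else:
            self._reduced_policy = None

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def damping(self) -> np.ndarray:
        """Depth-dependent soil-temperature damping: faster near the
        surface, slower at depth (e-folding 25 cm)."""
        mids = np.array([(h.upper_cm + h.lower_cm) / 2 for h in self.profile.horizons])
        return np.clip(0.5 * np.exp(-mids / 25.0), 0.02, 1.0)

    def build_weather(self) -> pd.DataFrame:
        """The forcing series for the horizon, with scenario deltas applied."""
        if self.weather is not None:
            series = self.weather
        else:
            stats = self.gen_stats if self.gen_stats is not None else cfg.default_generator_stats()
            series = wx.generate_daily_weather(stats, self.years, self.seed, self.start_year)
        return wx.apply_climate_deltas(series, self.scenario)


@dataclass
class SimulationResult:
    daily: pd.DataFrame
    events: pd.DataFrame
    annual: pd.DataFrame
    config: SimulationConfig


EVENT_COLUMNS = ["date", "kind", "trigger", "harvest_kg_dm_ha", "N_kg_ha",
                 "C_kg_ha", "cut_index", "year", "doy"]


def _co2_clamped(year: float, spec: wx.ScenarioSpec) -> float:
    years = sorted(spec.co2_anchors)
    y = min(max(year, years[0]), years[-1])
    return wx.co2_at(y, spec)


class _ManureWindow:
    """Pending slurry application: opened at season start (slot 0) or after
    cut k (slot k); closed when served, superseded or expired."""

    __slots__ = ("slot", "open_doy")

    def __init__(self, slot: int, open_doy: int):
        self.slot = slot
        self.open_doy = open_doy


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run one simulation: spin-up (recycled first years, unlogged) followed
    by the reported horizon.  Deterministic for a fixed seed."""
    weather_df = config.build_weather()
    dates = pd.DatetimeIndex(weather_df["date"])
    if len(dates) == 0:
        raise ValueError("empty forcing series")

    params = config.params
    profile = config.profile
    rules = config.rules
    damping = config.damping()

    # effective post-cut manure exclusions for the unrestricted dynamic mode
    exclusions = set(rules.manure_after_cut_exclusions)
    if rules.exclude_after_final_nominal_cut:
        exclusions.add(config.target_model.nominal_cuts)

    plant = pl.PlantState()
    soil = profile.initial_state(n_mineral=config.initial_n_mineral,
                                 n_organic=config.initial_n_organic)
    tracker = sl.NCapTracker()
    air_run = 0.0  # running-mean air temperature driving soil temperature

    top = profile.horizons[0]
    psi_wilt, psi_field = top.wilting_point, top.field_capacity

    daily_rows: list[dict] = []
    events: list[mgmt.ManagementEvent] = []
    annual_rows: list[dict] = []

    # spin-up replays the first years of forcing without logging
    n_spin_days = int((dates.year < dates.year[0] + config.spinup_years).sum()) \
        if config.spinup_years > 0 else 0
    spin_index = list(range(min(n_spin_days, len(dates))))
    full_index = list(range(len(dates)))

    for phase, index in (("spinup", spin_index), ("main", full_index)):
        logging = phase == "main"
        # management state resets between phases (fresh calendar year)
        last_cut_doy: Optional[int] = None
        cut_index = 1
        window: Optional[_ManureWindow] = None
        tracker.reset()
        year_acc = _new_year_acc()

        tmins = weather_df["tmin"].to_numpy()
        tmaxs = weather_df["tmax"].to_numpy()
        precips = weather_df["precip"].to_numpy()
        rads = weather_df["rad"].to_numpy()

        for i in index:
            date = dates[i]
            doy = int(date.dayofyear)
            year = int(date.year)
            days_in_year = 366 if date.is_leap_year else 365
            wd = wx.WeatherDay(date, tmins[i], tmaxs[i], precips[i], rads[i])
            t_mean = wd.tmean

            if doy == 1:
                last_cut_doy = None
                cut_index = 1
                window = None
                tracker.reset()
                if logging and year_acc["days"] > 0:
                    annual_rows.append(_close_year(year_acc))
                year_acc = _new_year_acc()
                year_acc["year"] = year

            if year_acc["year"] is None:
                year_acc["year"] = year

            # --- physical environment -------------------------------------
            snow = sl.snow_and_frost_flags(soil, wd, config.melt_factor)
            soil = snow.state
            air_run = 0.8 * air_run + 0.2 * t_mean
            soil = sl.soil_temperature_step(
                soil, air_run, damping,
                config.snow_insulation if snow.snow_cover else 1.0)
            soil_t_top = float(soil.temperature[0])

            plant, season_started = pl.season_transition(
                plant, t_mean, doy, days_in_year, params)
            if season_started:
                year_acc["season_start_doy"] = doy
                if config.mode != "static":
                    allowed = (config._reduced_policy is None
                               or 0 in config._reduced_policy.allowed_slots)
                    if allowed:
                        window = _ManureWindow(0, doy)
            if plant.season_active:
                plant = pl.update_development(plant, t_mean, params)

            psi = soil.root_zone_psi(profile, config.root_depth_cm)

            # --- hourly canopy carbon fluxes ------------------------------
            t_h = wx.diurnal_temperature_cycle(wd.tmin, wd.tmax)
            rad_h = wx.solar_radiation_cycle(wd.rad, doy, config.latitude)
            par_h = params.kernel.par_fraction * rad_h
            co2 = _co2_clamped(year + (doy - 1) / days_in_year, config.scenario)

            arub, fp_d, fp_t, fp_n = pl.rubisco_activity(
                plant, psi, psi_wilt, psi_field, t_h, params)
            lai = plant.lai(params)
            gpp_h = pl.gross_photosynthesis(lai, par_h, co2, arub, params.kernel)
            gpp = float(np.sum(gpp_h))

            theta = pl.allocation_fractions(plant, params)
            rg, rm, exud = pl.respiration_and_exudation(plant, gpp, t_h, theta, params)
            rm_total = sum(rm.values())

            plant_c_before = params.c_to_dm * plant.total_mass
            assim = gpp - rg - rm_total - exud
            if assim >= 0:
                growth = assim / params.c_to_dm
                for x in pl.COMPARTMENTS:
                    plant.set_mass(x, plant.mass(x) + growth * theta[x])
            else:
                deficit_c = -assim
                available_c = params.c_to_dm * plant.total_mass
                if deficit_c > available_c:
                    # starving sward: maintenance respiration cannot burn
                    # more carbon than exists; scale it down
                    scale = available_c / deficit_c if deficit_c > 0 else 0.0
                    rg *= scale
                    exud *= scale
                    for x in rm:
                        rm[x] *= scale
                    rm_total = sum(rm.values())
                    deficit_c = available_c
                _drain_carbon(plant, deficit_c / params.c_to_dm)

            # --- senescence -----------------------------------------------
            losses, fs_d, fs_f, fs_a = pl.senescence(
                plant, psi, psi_wilt, psi_field, t_mean, soil_t_top, params)
            litter_n_day = 0.0
            sen_total = 0.0
            for x, loss in losses.items():
                c_n = plant.c_n(x, params)
                plant.set_mass(x, plant.mass(x) - loss)
                litter_n_day += loss * c_n
                sen_total += loss
            litter_n_day = min(litter_n_day, plant.plant_n)
            plant.plant_n -= litter_n_day
            plant.litter_dm += sen_total
            plant.litter_n += litter_n_day
            soil.n_organic += litter_n_day  # litter N recycles into the slow pool

            # --- nitrogen -------------------------------------------------
            soil, mineralized = sl.mineralize(
                soil, soil_t_top, psi, psi_wilt, psi_field,
                config.mineralization_rate, params.limit, params.t_ref)
            plant, n_uptake, n_surplus = pl.redistribute_nitrogen(
                plant, soil.n_mineral, params)
            soil.n_mineral += n_surplus - n_uptake

            # --- water ----------------------------------------------------
            pet = sl.potential_evapotranspiration(wd)
            demand = pet * min(1.0, lai / 3.0)
            storage_before = float(soil.water_mm.sum())
            soil, fluxes = sl.step_water_balance(
                soil, profile, snow.liquid_mm, pet, demand,
                config.interception_capacity, config.root_depth_cm)
            w_residual = snow.liquid_mm - (fluxes.interception + fluxes.et
                                           + fluxes.percolation
                                           + (float(soil.water_mm.sum()) - storage_before))

            # --- management (end of day) ----------------------------------
            harvest = 0.0
            harvest_n = 0.0
            if config.mode == "static":
                harvest, harvest_n, window = _static_management(
                    config, plant, soil, tracker, doy, date, events, logging)
            else:
                harvest, harvest_n, last_cut_doy, cut_index, window = _dynamic_management(
                    config, plant, soil, tracker, rules, exclusions, snow, wd,
                    doy, date, last_cut_doy, cut_index, window, events, logging)

            # --- closure & logging ----------------------------------------
            plant_c_after = params.c_to_dm * plant.total_mass
            c_residual = (plant_c_after - plant_c_before
                          - (gpp - rg - rm_total - exud)
                          + params.c_to_dm * (sen_total + harvest))

            year_acc["days"] += 1
            year_acc["harvest"] += harvest
            year_acc["n_applied"] = tracker.annual_n
            if 3 <= date.month <= 10:
                year_acc["gs_precip"] += wd.precip
                year_acc["gs_t_sum"] += t_mean
                year_acc["gs_days"] += 1
            if harvest > 0:
                year_acc["cuts"] += 1
                if year_acc["first_cut_doy"] is None:
                    year_acc["first_cut_doy"] = doy

            if logging:
                daily_rows.append({
                    "date": date, "year": year, "doy": doy,
                    "tmin": wd.tmin, "tmax": wd.tmax, "precip": wd.precip,
                    "rad": wd.rad, "co2": co2, "swe": soil.swe_mm,
                    "psi_root": psi, "soil_t_top": soil_t_top,
                    "m_leaf": plant.m_leaf, "m_stem": plant.m_stem,
                    "m_root": plant.m_root, "m_storage": plant.m_storage,
                    "lai": lai, "dvs": plant.dvs,
                    "season_active": plant.season_active,
                    "gpp": gpp, "rg": rg, "rm": rm_total, "exudation": exud,
                    "senescence": sen_total,
                    "fp_drought": fp_d, "fp_nitrogen": fp_n,
                    "n_mineral": soil.n_mineral, "n_organic": soil.n_organic,
                    "plant_n": plant.plant_n, "n_uptake": n_uptake,
                    "mineralized": mineralized,
                    "pet": pet, "et": fluxes.et,
                    "interception": fluxes.interception,
                    "percolation": fluxes.percolation,
                    "harvest": harvest, "harvest_n": harvest_n,
                    "c_residual": c_residual, "w_residual": w_residual,
                })

    if year_acc["days"] > 0:
        annual_rows.append(_close_year(year_acc))

    daily = pd.DataFrame(daily_rows)
    ev = pd.DataFrame(
        [{
            "date": e.date, "kind": e.kind, "trigger": e.trigger,
            "harvest_kg_dm_ha": e.harvest_dm, "N_kg_ha": e.n_applied,
            "C_kg_ha": e.c_applied, "cut_index": e.cut_index,
            "year": e.date.year, "doy": int(e.date.dayofyear),
        } for e in events],
        columns=EVENT_COLUMNS,
    )
    annual = pd.DataFrame(annual_rows)
    return SimulationResult(daily, ev, annual, config)


def _drain_carbon(plant: pl.PlantState, deficit_dm: float) -> None:
    """Remove dry matter to cover a carbon deficit: storage first, the rest
    proportionally from the other compartments."""
    take = min(plant.m_storage, deficit_dm)
    plant.m_storage -= take
    deficit_dm -= take
    if deficit_dm <= 0:
        return
    rest = plant.m_root + plant.m_leaf + plant.m_stem
    if rest <= 0:
        return
    f = min(1.0, deficit_dm / rest)
    for x in ("root", "leaf", "stem"):
        plant.set_mass(x, plant.mass(x) * (1.0 - f))


def _new_year_acc() -> dict:
    return {"year": None, "days": 0, "cuts": 0, "first_cut_doy": None,
            "season_start_doy": None, "harvest": 0.0, "n_applied": 0.0,
            "gs_precip": 0.0, "gs_t_sum": 0.0, "gs_days": 0}


def _close_year(acc: dict) -> dict:
    return {
        "year": acc["year"],
        "cuts": acc["cuts"],
        "first_cut_doy": acc["first_cut_doy"],
        "season_start_doy": acc["season_start_doy"],
        "harvest_kg_dm_ha": acc["harvest"],
        "n_applied_kg_ha": acc["n_applied"],
        "gs_precip_mm": acc["gs_precip"],
        "gs_mean_t": acc["gs_t_sum"] / acc["gs_days"] if acc["gs_days"] else np.nan,
    }


def _static_management(config, plant, soil, tracker, doy, date, events, logging):
    """Fixed yearly calendar: cuts and manure on the template DOYs."""
    schedule = config.static_schedule
    params = config.params
    rules = config.rules
    harvest = harvest_n = 0.0
    window = None
    if doy in schedule.cut_doys:
        harvest, harvest_n, _ = pl.apply_cut(
            plant, rules.residual_leaf, rules.residual_stem, params)
        if logging:
            idx = list(schedule.cut_doys).index(doy) + 1
            events.append(mgmt.ManagementEvent(date, "cut", "static",
                                               harvest_dm=harvest, cut_index=idx))
    if doy in schedule.manure_doys:
        comp = schedule.composition
        st = sl.apply_manure(soil, comp, tracker)
        soil.n_mineral, soil.n_organic = st.n_mineral, st.n_organic
        if logging:
            events.append(mgmt.ManagementEvent(date, "manure", "static",
                                               n_applied=comp.n_load,
                                               c_applied=comp.c_load))
    return harvest, harvest_n, window


def _dynamic_management(config, plant, soil, tracker, rules, exclusions, snow,
                        wd, doy, date, last_cut_doy, cut_index, window, events,
                        logging):
    """On-the-fly rule engine: cut decision first, then the pending manure
    window (a new cut supersedes an unserved post-cut window)."""
    params = config.params
    harvest = harvest_n = 0.0
    if plant.season_active:
        harvestable = max(0.0, plant.aboveground - rules.residual_total)
        do_cut, trigger = mgmt.cut_decision(doy, harvestable, last_cut_doy,
                                            cut_index, rules, config.target_model)
        if do_cut:
            harvest, harvest_n, _ = pl.apply_cut(
                plant, rules.residual_leaf, rules.residual_stem, params)
            if logging:
                events.append(mgmt.ManagementEvent(date, "cut", trigger,
                                                   harvest_dm=harvest,
                                                   cut_index=cut_index))
            this_cut = cut_index
            last_cut_doy = doy
            cut_index += 1
            # open (or supersede with) the post-cut manure window
            policy = config._reduced_policy
            if policy is not None:
                allowed = this_cut in policy.allowed_slots
            else:
                allowed = this_cut not in exclusions
                if rules.exclude_after_final_nominal_cut and \
                        this_cut >= config.target_model.nominal_cuts:
                    allowed = False
            window = _ManureWindow(this_cut, doy) if allowed else None

    if window is not None:
        comp = (config._reduced_policy.composition
                if config._reduced_policy is not None else config.composition)
        apply, reason = mgmt.manure_decision(
            doy, window.open_doy, window.slot == 0, snow.snow_cover,
            snow.soil_frozen, wd.precip, rules, tracker.annual_n, comp)
        if apply:
            st = sl.apply_manure(soil, comp, tracker)
            soil.n_mineral, soil.n_organic = st.n_mineral, st.n_organic
            if logging:
                events.append(mgmt.ManagementEvent(date, "manure", reason,
                                                   n_applied=comp.n_load,
                                                   c_applied=comp.c_load,
                                                   cut_index=window.slot))
            window = None
        elif window.slot > 0 and doy - window.open_doy > rules.manure_window_days:
            # past the nominal window and still blocked by rain: keep
            # searching day by day, but give up at season end
            if doy >= rules.season_end_doy:
                window = None
    return harvest, harvest_n, last_cut_doy, cut_index, window


def run_scenario_ensemble(
    config: SimulationConfig,
    realizations: int = 10,
    seeds: Optional[Sequence[int]] = None,
) -> dict:
    """Run ``realizations`` weather realizations of one configuration and
    stack the annual summaries.

    Returns ``{"annual": stacked df, "quantiles": per-year median and
    25th/75th percentile of harvest, first-cut DOY, cut count and applied
    N}``.  A 5-year centred moving average of the median is included as
    ``*_ma5`` columns.
    """
    if realizations < 1:
        raise ValueError("need at least 1 realization")
    if seeds is None:
        seeds = [config.seed + i for i in range(realizations)]
    frames = []
    for r, seed in enumerate(seeds):
        res = run_simulation(config.replace(seed=int(seed), weather=None))
        a = res.annual.copy()
        a["realization"] = r
        frames.append(a)
    annual = pd.concat(frames, ignore_index=True)

    fields = ["harvest_kg_dm_ha", "first_cut_doy", "cuts", "n_applied_kg_ha"]
    g = annual.groupby("year")
    q = pd.DataFrame({"year": sorted(annual["year"].unique())}).set_index("year")
    for f in fields:
        q[f"{f}_median"] = g[f].median()
        q[f"{f}_q25"] = g[f].quantile(0.25)
        q[f"{f}_q75"] = g[f].quantile(0.75)
        q[f"{f}_ma5"] = q[f"{f}_median"].rolling(5, center=True, min_periods=1).mean()
    return {"annual": annual, "quantiles": q.reset_index()}


def compare_managements(
    configs: dict,
    shared_weather: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Run several management configurations on identical weather and return
    per-year paired yield differences.

    ``configs`` maps a label to a :class:`SimulationConfig`; all runs share
    the same forcing (``shared_weather`` or one generated from the first
    config's seed).  Output: one row per year with ``harvest_<label>`` and
    ``cuts_<label>`` columns plus pairwise differences against the first
    label.
    """
    if not configs:
        raise ValueError("no configurations given")
    labels = list(configs)
    base = configs[labels[0]]
    if shared_weather is None:
        shared_weather = base.build_weather() if base.weather is None else base.weather
    horizons = {label: (c.start_year, c.years) for label, c in configs.items()}
    if len(set(horizons.values())) != 1:
        raise ValueError(f"mismatched horizons: {horizons}")

    merged: Optional[pd.DataFrame] = None
    for label, c in configs.items():
        res = run_simulation(c.replace(weather=shared_weather))
        a = res.annual[["year", "harvest_kg_dm_ha", "cuts", "n_applied_kg_ha",
                        "first_cut_doy"]].rename(columns={
            "harvest_kg_dm_ha": f"harvest_{label}",
            "cuts": f"cuts_{label}",
            "n_applied_kg_ha": f"n_applied_{label}",
            "first_cut_doy": f"first_cut_doy_{label}",
        })
        merged = a if merged is None else merged.merge(a, on="year")
    ref = labels[0]
    for label in labels[1:]:
        merged[f"harvest_diff_{label}_vs_{ref}"] = (
            merged[f"harvest_{label}"] - merged[f"harvest_{ref}"])
    return merged
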