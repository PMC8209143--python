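"""Minimal soil environment for the grassland simulator.

A layered tipping-bucket water balance (water above field capacity cascades
to the next layer, bottom excess leaves as deep percolation), an exponential
soil-temperature relaxation, degree-day snow accumulation/melt with frost
flags, and a two-pool mineral-N bookkeeping (mineral + slow organic) fed by
slurry applications and first-order mineralization.  The module supplies the
plant model with root-zone volumetric water content, topsoil temperature and
plant-available mineral N; full soil biogeochemistry (nitrification,
denitrification, gaseous losses, leaching) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .weather import WeatherDay

__all__ = [
    "SoilHorizon",
    "SoilProfile",
    "SoilState",
    "ManureComposition",
    "NCapTracker",
    "WaterFluxes",
    "SnowResult",
    "potential_evapotranspiration",
    "step_water_balance",
    "soil_temperature_step",
    "snow_and_frost_flags",
    "apply_manure",
    "mineralize",
    "moisture_response",
    "temperature_response",
]

MINERAL_DENSITY = 2.65  # g/cm3, quartz-like particle density for porosity


@dataclass(frozen=True)
class SoilHorizon:
    """One soil horizon as listed in a site's soil survey table."""

    upper_cm: float
    lower_cm: float
    bulk_density: float        # g/cm3
    ph: float
    c_org: float               # weight-%
    n_org: float               # weight-%
    clay: float                # %
    silt: float                # %
    sand: float                # %
    field_capacity: float      # vol-%
    wilting_point: float       # vol-%
    hydraulic_conductivity: float = 0.01  # cm/min (not used by the bucket)
    stone_fraction: float = 0.0           # %

    def __post_init__(self) -> None:
        if self.lower_cm <= self.upper_cm:
            raise ValueError("horizon lower depth must exceed upper depth")
        if not self.wilting_point < self.field_capacity:
            raise ValueError("wilting point must be below field capacity")
        if abs(self.clay + self.silt + self.sand - 100.0) > 0.5:
            raise ValueError("texture fractions must sum to 100 +- 0.5")

    @property
    def thickness_cm(self) -> float:
        return self.lower_cm - self.upper_cm

    @property
    def saturation(self) -> float:
        """Porosity-based saturation (vol-%), never below field capacity."""
        porosity = (1.0 - self.bulk_density / MINERAL_DENSITY) * 100.0
        return max(porosity, self.field_capacity)


class SoilProfile:
    """Contiguous stack of horizons with derived per-layer water capacities."""

    def __init__(self, horizons: Sequence[SoilHorizon]):
        if not horizons:
            raise ValueError("profile needs at least one horizon")
        horizons = sorted(horizons, key=lambda h: h.upper_cm)
        for a, b in zip(horizons, horizons[1:]):
            if abs(a.lower_cm - b.upper_cm) > 1e-9:
                raise ValueError("horizons must be contiguous and non-overlapping")
        self.horizons = list(horizons)
        self.thickness_mm = np.array([h.thickness_cm * 10.0 for h in horizons])
        self.fc_mm = self.thickness_mm * np.array([h.field_capacity for h in horizons]) / 100.0
        self.wilt_mm = self.thickness_mm * np.array([h.wilting_point for h in horizons]) / 100.0
        self.sat_mm = self.thickness_mm * np.array([h.saturation for h in horizons]) / 100.0

    def __len__(self) -> int:
        return len(self.horizons)

    def root_zone_weights(self, root_depth_cm: float) -> np.ndarray:
        """Fraction of each layer inside the root zone (by thickness)."""
        w = np.zeros(len(self.horizons))
        for i, h in enumerate(self.horizons):
            overlap = max(0.0, min(h.lower_cm, root_depth_cm) - h.upper_cm)
            w[i] = overlap / h.thickness_cm
        return w

    def initial_state(self, at_field_capacity: bool = True,
                      n_mineral: float = 20.0, n_organic: float = 6000.0,
                      temperature: float = 5.0) -> "SoilState":
        water = self.fc_mm.copy() if at_field_capacity else self.wilt_mm.copy()
        return SoilState(
            water_mm=water,
            temperature=np.full(len(self.horizons), float(temperature)),
            swe_mm=0.0,
            n_mineral=float(n_mineral),
            n_organic=float(n_organic),
        )


@dataclass
class SoilState:
    """Mutable soil state: per-layer water (mm) and temperature (degC), snow
    water equivalent (mm), and the two nitrogen pools (kg N/ha)."""

    water_mm: np.ndarray
    temperature: np.ndarray
    swe_mm: float = 0.0
    n_mineral: float = 0.0
    n_organic: float = 0.0

    def copy(self) -> "SoilState":
        return SoilState(self.water_mm.copy(), self.temperature.copy(),
                         self.swe_mm, self.n_mineral, self.n_organic)

    def psi_vol(self, profile: SoilProfile) -> np.ndarray:
        """Per-layer volumetric water content (vol-%)."""
        return self.water_mm / profile.thickness_mm * 100.0

    def root_zone_psi(self, profile: SoilProfile, root_depth_cm: float = 30.0) -> float:
        """Thickness-weighted volumetric water content over the root zone."""
        w = profile.root_zone_weights(root_depth_cm) * profile.thickness_mm
        if w.sum() <= 0:
            raise ValueError("root zone does not intersect the profile")
        return float((self.psi_vol(profile) * w).sum() / w.sum())


@dataclass(frozen=True)
class ManureComposition:
    """Slurry characterization: C and N loads per event, pH and N speciation.

    Speciation fractions (ammonium, nitrate, urea, dissolved organic N) must
    sum to 1; NH4+NO3+urea is treated as immediately plant-available mineral
    N, DON feeds the slow organic pool.
    """

    c_load: float = 437.0          # kg C/ha per event
    n_load: float = 48.0           # kg N/ha per event
    ph: float = 7.6
    frac_nh4: float = 0.45
    frac_no3: float = 0.05
    frac_urea: float = 0.10
    frac_don: float = 0.40

    def __post_init__(self) -> None:
        if self.c_load < 0 or self.n_load < 0:
            raise ValueError("manure loads must be >= 0")
        fracs = (self.frac_nh4, self.frac_no3, self.frac_urea, self.frac_don)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("speciation fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("speciation fractions must sum to 1")

    @property
    def mineral_fraction(self) -> float:
        return self.frac_nh4 + self.frac_no3 + self.frac_urea

    def scaled(self, factor: float) -> "ManureComposition":
        """Composition with C and N loads scaled by ``factor`` (speciation
        and pH unchanged); used by the reduced-N policy."""
        return ManureComposition(self.c_load * factor, self.n_load * factor, self.ph,
                                 self.frac_nh4, self.frac_no3, self.frac_urea, self.frac_don)


@dataclass
class NCapTracker:
    """Running total of fertilizer N applied in the current calendar year."""

    annual_n: float = 0.0

    def reset(self) -> None:
        self.annual_n = 0.0


class WaterFluxes(NamedTuple):
    interception: float   # mm, evaporated from the canopy
    et: float             # mm, soil water extracted (transpiration + evaporation)
    percolation: float    # mm, deep drainage out of the profile


class SnowResult(NamedTuple):
    snow_cover: bool
    soil_frozen: bool
    state: SoilState
    liquid_mm: float      # rain + melt reaching the soil surface


def potential_evapotranspiration(weather: WeatherDay) -> float:
    """Potential evapotranspiration (mm/d) from temperature and measured
    global radiation.

    A Hargreaves-type temperature x radiation formula,
    ``PET = 0.0135 (Tmean + 17.8) Rs`` with Rs the daily global radiation in
    evaporation-equivalent mm/d.  Chosen because the forcing carries no
    humidity or wind; monotone in both drivers and zero without radiation.
    """
    rs_mm = weather.rad * 0.0864 / 2.45  # W/m2 daily mean -> MJ/m2/d -> mm/d
    return max(0.0, 0.0135 * (weather.tmean + 17.8) * rs_mm)


def step_water_balance(
    state: SoilState,
    profile: SoilProfile,
    water_input_mm: float,
    pet_mm: float,
    transpiration_demand_mm: float,
    interception_capacity_mm: float = 1.0,
    root_depth_cm: float = 30.0,
) -> tuple[SoilState, WaterFluxes]:
    """One daily tipping-bucket step.

    ``water_input_mm`` is liquid water at the surface (rain plus snow melt).
    Interception (up to the capacity) evaporates; the rest infiltrates the
    top layer; water above field capacity cascades downward and leaves the
    bottom as deep percolation.  Actual ET is the smaller of the demand
    (itself capped at PET) and the water extractable above wilting in the
    root zone, removed proportionally to per-layer availability.
    Closes to machine precision: input = interception + ET + percolation +
    storage change.
    """
    if water_input_mm < 0 or pet_mm < 0 or transpiration_demand_mm < 0:
        raise ValueError("water fluxes must be >= 0")
    st = state.copy()

    interception = min(interception_capacity_mm, water_input_mm)
    infiltration = water_input_mm - interception

    percolation = 0.0
    carry = infiltration
    for i in range(len(profile)):
        st.water_mm[i] += carry
        carry = max(0.0, st.water_mm[i] - profile.fc_mm[i])
        st.water_mm[i] -= carry
    percolation = carry

    demand = min(transpiration_demand_mm, pet_mm)
    weights = profile.root_zone_weights(root_depth_cm)
    avail = np.maximum(0.0, (st.water_mm - profile.wilt_mm)) * weights
    total_avail = float(avail.sum())
    et = min(demand, total_avail)
    if et > 0 and total_avail > 0:
        extraction = avail * (et / total_avail)
        st.water_mm -= extraction
        et = float(extraction.sum())  # re-sum so closure is exact in floats

    return st, WaterFluxes(interception, et, percolation)


def soil_temperature_step(
    state: SoilState,
    air_t_daily_mean: float,
    damping_per_layer: Sequence[float],
    snow_insulation: float = 1.0,
) -> SoilState:
    """Relax each layer toward the driving air temperature:
    ``T <- T + d * (T_air - T)`` with per-layer damping d in (0, 1], deeper
    layers slower.  ``snow_insulation`` scales the damping (< 1 under snow).
    """
    d = np.asarray(damping_per_layer, dtype=float) * snow_insulation
    if np.any(d <= 0) or np.any(d > 1):
        raise ValueError("damping must lie in (0, 1]")
    st = state.copy()
    st.temperature = st.temperature + d * (air_t_daily_mean - st.temperature)
    return st


def snow_and_frost_flags(
    state: SoilState,
    weather: WeatherDay,
    melt_factor: float = 2.0,
) -> SnowResult:
    """Partition precipitation into snow/rain, melt by degree days, and flag
    snow cover and frozen topsoil.

    Precipitation at daily mean temperature < 0 degC accumulates as snow
    water equivalent; above 0 degC existing snow melts at ``melt_factor``
    mm per degC per day.  Snow cover means SWE > 0 after the update; frozen
    soil means topsoil temperature < 0 degC.
    """
    st = state.copy()
    t = weather.tmean
    if t < 0.0:
        st.swe_mm += weather.precip
        liquid = 0.0
    else:
        melt = min(st.swe_mm, melt_factor * t)
        st.swe_mm -= melt
        liquid = weather.precip + melt
    snow_cover = st.swe_mm > 0.0
    soil_frozen = bool(st.temperature[0] < 0.0)
    return SnowResult(snow_cover, soil_frozen, st, liquid)


def apply_manure(
    state: SoilState,
    event: ManureComposition,
    n_cap_tracker: NCapTracker | None = None,
) -> SoilState:
    """Book a slurry application into the soil N pools.

    The mineral-equivalent speciation (NH4 + NO3 + urea) goes to the mineral
    pool, the DON share to the slow organic pool; the annual applied-N
    tracker is incremented by the full N load.  Whether the application is
    allowed (N cap, timing) is the scheduler's concern, not this function's.
    """
    st = state.copy()
    st.n_mineral += event.mineral_fraction * event.n_load
    st.n_organic += event.frac_don * event.n_load
    if n_cap_tracker is not None:
        n_cap_tracker.annual_n += event.n_load
    return st


def temperature_response(t: float, t_limit: float = 10.0, t_ref: float = 20.0) -> float:
    """Low-temperature ramp (0 below 0.8*t_limit, 1 at t_limit) combined with
    a Q10 = 2 dependency around ``t_ref`` - the same shape the plant model
    uses for maintenance respiration."""
    ramp = np.clip((t - 0.8 * t_limit) / (0.2 * t_limit), 0.0, 1.0)
    return float(ramp * 2.0 ** ((t - t_ref) / 10.0))


def moisture_response(psi: float, psi_wilt: float, psi_field: float) -> float:
    """Microbial moisture response with an optimum at 80 % of the
    plant-available range: linear 0 -> 1 over [wilting, 0.8], then declining
    to 0.6 at field capacity (wet soils slow mineralization)."""
    w = (psi - psi_wilt) / (psi_field - psi_wilt)
    w = min(max(w, 0.0), 1.0)
    if w <= 0.8:
        return w / 0.8
    return 1.0 - 2.0 * (w - 0.8)  # 1 at w=0.8 -> 0.6 at w=1


def mineralize(
    state: SoilState,
    soil_t: float,
    psi: float,
    psi_wilt: float,
    psi_field: float,
    rate_per_day: float,
    t_limit: float = 10.0,
    t_ref: float = 20.0,
) -> tuple[SoilState, float]:
    """First-order transfer from the slow organic to the mineral N pool,
    modulated by temperature and moisture; mass-conserving between pools.
    Returns the updated state and the transferred amount (kg N/ha/d)."""
    if rate_per_day < 0:
        raise ValueError("mineralization rate must be >= 0")
    st = state.copy()
    f = rate_per_day * temperature_response(soil_t, t_limit, t_ref) \
        * moisture_response(psi, psi_wilt, psi_field)
    transfer = min(st.n_organic, st.n_organic * f)
    st.n_organic -= transfer
    st.n_mineral += transfer
    return st, transfer
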