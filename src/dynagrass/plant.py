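"""Grassland plant growth core.

A four-compartment (leaf, stem, root, storage) sward model driven by hourly
temperature and light and by daily soil water and mineral nitrogen:

* phenology as growing degree days normalized to a development state DVS;
* dynamic carbon allocation with a development-dependent storage share, a
  root share damped before the first cut of the season, and a leaf/stem
  split steering toward a species-specific stem mass fraction;
* gross photosynthesis from a saturating light/CO2/LAI kernel scaled by a
  rubisco-activity factor that aggregates drought, low-temperature and
  nitrogen limitation;
* growth respiration as a fixed fraction of GPP, Q10 maintenance
  respiration per compartment, and root exudation as a fraction of the
  root-assigned growth respiration;
* senescence as the maximum of drought, frost and age response rates (air
  temperature drives the aboveground, soil temperature the belowground
  compartments);
* instantaneous nitrogen redistribution toward compartment-specific optimum
  concentrations, with uptake limited by soil supply and a daily cap;
* cutting: aboveground biomass above the residual is exported, the storage
  pool is fully translocated, and allocation switches to its post-first-cut
  regime.

All biomasses are kg dry matter (DM) per hectare; carbon fluxes are kg C per
hectare; the carbon content of dry matter is a configurable constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "COMPARTMENTS",
    "PlantParams",
    "PhotosynthesisKernel",
    "PlantState",
    "GrowthFluxes",
    "update_development",
    "allocation_fractions",
    "drought_response",
    "temperature_ramp",
    "rubisco_activity",
    "gross_photosynthesis",
    "respiration_and_exudation",
    "senescence",
    "redistribute_nitrogen",
    "apply_cut",
    "season_transition",
]

COMPARTMENTS = ("storage", "root", "leaf", "stem")


@dataclass(frozen=True)
class PhotosynthesisKernel:
    """Saturating light/CO2 response of canopy gross photosynthesis.

    ``GPP = amax * arubisco * (1 - exp(-k_ext * LAI)) * PAR/(PAR + par_half)
    * fCO2`` with ``fCO2`` a Michaelis factor normalized to 1 at 400 ppm.
    ``amax`` is the canopy-scale maximum assimilation (kg C/ha/h) at closed
    canopy, saturating light and 400 ppm.
    """

    amax: float = 66.0          # kg C/ha/h
    par_half: float = 250.0     # W/m2 PAR half-saturation
    co2_half: float = 300.0     # ppm Michaelis constant
    k_ext: float = 0.5          # canopy light extinction
    par_fraction: float = 0.5   # PAR share of global radiation

    def co2_factor(self, co2_ppm: float) -> float:
        ref = 400.0 / (400.0 + self.co2_half)
        return (co2_ppm / (co2_ppm + self.co2_half)) / ref


@dataclass(frozen=True)
class PlantParams:
    """Species-specific parameter vector of the sward model.

    The shipped defaults (``data/plant_default.yaml``) are a calibration
    fixture for an intensively cut (4-5 cuts/yr) pre-alpine grassland
    mixture; see the calibration script and the methods note.
    """

    # carbon allocation weights (unitless)
    storage: float = 0.45
    root: float = 0.90
    leaf: float = 0.42
    stem: float = 0.18
    cut: float = 0.4            # root-allocation multiplier before first cut
    # phenology
    gdd: float = 1000.0         # degC d for full development
    t_base: float = 4.0         # degC base temperature
    gdd_onset: float = 70.0    # degC d from Jan 1 to season onset
    # canopy / photosynthesis
    sla: float = 20.0           # m2 per kg DM leaf
    rubisco: float = 1.0        # maximum rubisco activity scaler
    h2o: float = 0.5            # drought-stress factor (photosynthesis)
    h2o_sen: float = 0.35       # drought-stress factor (senescence)
    limit: float = 8.0         # degC critical temperature
    # nitrogen
    nc_storage: float = 0.015   # kg N per kg DM
    nc_root: float = 0.012
    nc_leaf: float = 0.028
    nc_stem: float = 0.012
    ndef_leaf: float = 2.0      # N-limitation exponent
    n_uptake_max: float = 6.0   # kg N/ha/d uptake cap
    # respiration / exudation
    yield_frac: float = 0.25    # growth-respiration fraction of GPP
    r_storage: float = 0.002   # maintenance coefficients (1/d at t_ref)
    r_root: float = 0.0075
    r_leaf: float = 0.015
    r_stem: float = 0.009
    t_ref: float = 20.0         # degC Q10 reference
    exudate: float = 0.20       # fraction of root growth respiration
    # senescence
    sen_drought: float = 0.03   # 1/d maximal drought senescence
    sen_frost: float = 0.006    # 1/(degC d) frost senescence slope
    sen_age: float = 0.006     # 1/d age senescence
    # conversions & kernel
    c_to_dm: float = 0.45       # kg C per kg DM
    kernel: PhotosynthesisKernel = field(default_factory=PhotosynthesisKernel)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)):
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"plant parameter {f.name} must be finite and >= 0")
        if self.gdd <= 0:
            raise ValueError("gdd must be > 0")
        for x in COMPARTMENTS:
            if getattr(self, f"nc_{x}") <= 0:
                raise ValueError(f"nc_{x} must be > 0")
        if self.root + self.leaf + self.stem <= 0:
            raise ValueError("allocation weights must not all be zero")

    def nc(self, comp: str) -> float:
        return getattr(self, f"nc_{comp}")

    def r_maint(self, comp: str) -> float:
        return getattr(self, f"r_{comp}")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "PlantParams":
        kernel_kwargs = dict(d.get("kernel", {}))
        kwargs = {k.lower(): v for k, v in d.items() if k.lower() != "kernel"}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown plant parameters: {sorted(unknown)}")
        if kernel_kwargs:
            kwargs["kernel"] = PhotosynthesisKernel(**kernel_kwargs)
        return cls(**kwargs)


@dataclass
class PlantState:
    """Live sward state the daily loop and the scheduler inspect."""

    m_storage: float = 800.0
    m_root: float = 2000.0
    m_leaf: float = 100.0
    m_stem: float = 40.0
    plant_n: float = 0.0        # kg N/ha total plant nitrogen
    gdd: float = 0.0            # accumulated degree days within the season
    annual_gdd: float = 0.0     # accumulated from Jan 1 (season onset)
    dvs: float = 0.0
    first_cut_done: bool = False
    season_active: bool = False
    litter_dm: float = 0.0      # cumulative senescence losses (kg DM/ha)
    litter_n: float = 0.0       # N exported to litter (kg N/ha)

    def __post_init__(self) -> None:
        if self.plant_n == 0.0:
            # start at half the optimum concentrations
            self.plant_n = 0.5 * sum(self.mass(x) * 0.02 for x in COMPARTMENTS)

    def mass(self, comp: str) -> float:
        return getattr(self, f"m_{comp}")

    def set_mass(self, comp: str, value: float) -> None:
        setattr(self, f"m_{comp}", value)

    @property
    def total_mass(self) -> float:
        return self.m_storage + self.m_root + self.m_leaf + self.m_stem

    @property
    def aboveground(self) -> float:
        return self.m_leaf + self.m_stem

    def n_target(self, params: PlantParams) -> float:
        return sum(self.mass(x) * params.nc(x) for x in COMPARTMENTS)

    def n_fill(self, params: PlantParams) -> float:
        """Ratio of actual to optimum plant N (capped at 1)."""
        target = self.n_target(params)
        if target <= 0:
            return 1.0
        return min(1.0, self.plant_n / target)

    def c_n(self, comp: str, params: PlantParams) -> float:
        """Actual N concentration of a compartment (kg N per kg DM).

        Nitrogen is redistributed instantaneously in proportion to each
        compartment's demand, so concentrations share a common fill ratio.
        """
        target = self.n_target(params)
        if target <= 0 or self.mass(comp) <= 0:
            return params.nc(comp)
        return params.nc(comp) * self.plant_n / target

    def lai(self, params: PlantParams) -> float:
        return self.m_leaf * params.sla / 1.0e4  # kg/ha * m2/kg / (m2/ha)

    def copy(self) -> "PlantState":
        return dataclasses.replace(self)


@dataclass
class GrowthFluxes:
    """Daily diagnostic fluxes (kg C/ha/d unless noted)."""

    gpp: float = 0.0
    rg: float = 0.0
    rm: dict = field(default_factory=dict)
    exudation: float = 0.0
    senescence_dm: dict = field(default_factory=dict)  # kg DM/ha/d
    theta: dict = field(default_factory=dict)
    arubisco: float = 0.0
    fp_drought: float = 0.0
    fp_temp: float = 0.0
    fp_nitrogen: float = 0.0
    fs_drought: float = 0.0
    fs_frost: float = 0.0
    fs_age: float = 0.0
    n_demand: float = 0.0      # kg N/ha
    n_uptake: float = 0.0      # kg N/ha/d


# ---------------------------------------------------------------------------
# development & allocation


def update_development(state: PlantState, daily_mean_t: float, params: PlantParams) -> PlantState:
    """Accumulate growing degree days and update the development state
    DVS = min(GDD / gdd_full, 1).  Only meaningful within the season."""
    inc = max(0.0, daily_mean_t - params.t_base)
    state.gdd += inc
    state.dvs = min(state.gdd / params.gdd, 1.0)
    return state


def allocation_fractions(state: PlantState, params: PlantParams) -> dict[str, float]:
    """Realized allocation fractions of assimilated carbon.

    The storage share grows linearly with DVS; the root share takes its
    weight (damped by the pre-first-cut multiplier) relative to the
    aboveground weights; the remainder is split between leaf and stem by a
    proportional-controller step toward the target stem mass fraction
    stem_w / (leaf_w + stem_w).  Fractions sum to exactly 1.
    """
    theta_storage = state.dvs * params.storage
    gamma = params.cut if not state.first_cut_done else 1.0
    denom = params.root * gamma + params.leaf + params.stem
    theta_root = (1.0 - theta_storage) * params.root * gamma / denom
    rem = 1.0 - theta_storage - theta_root

    s_target = params.stem / (params.leaf + params.stem)
    ag = state.m_leaf + state.m_stem
    s_now = state.m_stem / ag if ag > 0 else s_target
    stem_share = min(max(2.0 * s_target - s_now, 0.0), 1.0)
    theta_stem = rem * stem_share
    theta_leaf = rem - theta_stem
    return {
        "storage": theta_storage,
        "root": theta_root,
        "leaf": theta_leaf,
        "stem": theta_stem,
    }


# ---------------------------------------------------------------------------
# photosynthesis limitation


def drought_response(psi: float, psi_wilt: float, psi_field: float, h2o: float) -> float:
    """Soil-moisture limitation: 0 at/below wilting, rising linearly and
    saturating at 1 once (psi - wilt) reaches h2o * (field - wilt)."""
    if psi <= psi_wilt:
        return 0.0
    return min(1.0, (psi - psi_wilt) / (h2o * (psi_field - psi_wilt)))


def temperature_ramp(t, limit: float):
    """Low-temperature photosynthesis/respiration ramp: 0 at 0.8*limit,
    1 at and above the critical temperature; clamped to [0, 1]."""
    return np.clip((np.asarray(t, dtype=float) - 0.8 * limit) / (0.2 * limit), 0.0, 1.0)


def rubisco_activity(
    state: PlantState,
    psi: float,
    psi_wilt: float,
    psi_field: float,
    hourly_t,
    params: PlantParams,
):
    """Rubisco activity and its component limitations.

    Returns ``(arubisco, fp_drought, fp_temp, fp_nitrogen)``; ``fp_temp``
    (and hence ``arubisco``) has the shape of ``hourly_t``.
    """
    if not psi_wilt < psi_field:
        raise ValueError("wilting point must be below field capacity")
    fp_drought = drought_response(psi, psi_wilt, psi_field, params.h2o)
    fp_temp = temperature_ramp(hourly_t, params.limit)
    ratio = state.c_n("leaf", params) / params.nc_leaf
    fp_nitrogen = min(1.0, ratio ** params.ndef_leaf)
    arub = params.rubisco * fp_drought * fp_temp * fp_nitrogen
    return arub, fp_drought, fp_temp, fp_nitrogen


def gross_photosynthesis(lai: float, par, co2_ppm: float, arubisco,
                         kernel: PhotosynthesisKernel):
    """Canopy gross photosynthesis (kg C/ha/h), elementwise over hours.

    Zero without light, leaf area or rubisco activity; strictly increasing
    and saturating in PAR, CO2 and LAI; exactly multiplicative in the
    rubisco activity.
    """
    if lai < 0:
        raise ValueError("LAI must be >= 0")
    par = np.asarray(par, dtype=float)
    light = par / (par + kernel.par_half)
    canopy = 1.0 - np.exp(-kernel.k_ext * lai)
    return kernel.amax * np.asarray(arubisco) * canopy * light * kernel.co2_factor(co2_ppm)


# ---------------------------------------------------------------------------
# respiration, exudation, senescence


def respiration_and_exudation(
    state: PlantState,
    gpp: float,
    hourly_t,
    theta: Mapping[str, float],
    params: PlantParams,
):
    """Growth respiration, per-compartment maintenance respiration and root
    exudation for one day.

    ``Rg = yield_frac * GPP`` (assigned to compartments by theta);
    ``Rm_x = m_x * r_x * ramp(T) * 2**((T - t_ref)/10)`` integrated over the
    24 hourly temperatures; exudation is a fraction of the root-assigned
    growth respiration.  All in kg C/ha/d.
    """
    if gpp < 0:
        raise ValueError("GPP must be >= 0")
    t = np.asarray(hourly_t, dtype=float)
    rg = params.yield_frac * gpp
    # mean over the hourly temperature response; coefficients are per day
    f = float(np.mean(temperature_ramp(t, params.limit) * 2.0 ** ((t - params.t_ref) / 10.0)))
    rm = {x: state.mass(x) * params.c_to_dm * params.r_maint(x) * f for x in COMPARTMENTS}
    exudation = params.exudate * theta["root"] * rg
    return rg, rm, exudation


def senescence(
    state: PlantState,
    psi: float,
    psi_wilt: float,
    psi_field: float,
    air_t: float,
    soil_t: float,
    params: PlantParams,
):
    """Daily senescence losses per compartment (kg DM/ha/d).

    The effective rate is the maximum of the drought, frost and age response
    rates; air temperature drives frost senescence of leaf and stem, soil
    temperature that of root and storage.  Losses are capped at the
    available mass.  Returns ``(losses, fs_drought, fs_frost_air, fs_age)``.
    """
    if psi > psi_wilt:
        sat = min(1.0, (psi - psi_wilt) / (params.h2o_sen * (psi_field - psi_wilt)))
        fs_drought = params.sen_drought * (1.0 - sat)
    else:
        # continuity: maximal drought senescence at/below wilting
        fs_drought = params.sen_drought

    def frost(t: float) -> float:
        return params.sen_frost * abs(t) if t < 0.0 else 0.0

    fs_age = params.sen_age
    rate_above = max(fs_drought, frost(air_t), fs_age)
    rate_below = max(fs_drought, frost(soil_t), fs_age)
    losses = {}
    for x in COMPARTMENTS:
        rate = rate_above if x in ("leaf", "stem") else rate_below
        losses[x] = min(state.mass(x), rate * state.mass(x))
    return losses, fs_drought, frost(air_t), fs_age


# ---------------------------------------------------------------------------
# nitrogen


def redistribute_nitrogen(
    state: PlantState,
    available_mineral_n: float,
    params: PlantParams,
) -> tuple[PlantState, float, float]:
    """Take up mineral N toward the optimum concentrations and re-spread
    plant N across compartments in proportion to demand.

    Uptake = min(deficit, available, daily cap).  If plant N exceeds the
    optimum total (e.g. after mass loss) the surplus is returned to the soil
    so concentrations never exceed the optima.  Returns
    ``(state, uptake, surplus_returned)``.
    """
    if available_mineral_n < 0:
        raise ValueError("available mineral N must be >= 0")
    target = state.n_target(params)
    deficit = max(0.0, target - state.plant_n)
    uptake = min(deficit, available_mineral_n, params.n_uptake_max)
    state.plant_n += uptake
    surplus = max(0.0, state.plant_n - target)
    state.plant_n -= surplus
    return state, uptake, surplus


# ---------------------------------------------------------------------------
# cutting & season


def apply_cut(
    state: PlantState,
    residual_leaf_mass: float,
    residual_stem_mass: float,
    params: PlantParams,
) -> tuple[float, float, PlantState]:
    """Harvest aboveground biomass down to the residuals.

    Exported N leaves at the current compartment concentrations; the first-cut
    flag flips (allocation switches to its post-cut regime) and the storage
    pool is fully translocated according to the then-current allocation
    fractions (renormalized over the non-storage compartments).  Returns
    ``(harvested_dm, harvested_n, state)``.
    """
    if residual_leaf_mass < 0 or residual_stem_mass < 0:
        raise ValueError("residual masses must be >= 0")
    cut_leaf = max(0.0, state.m_leaf - residual_leaf_mass)
    cut_stem = max(0.0, state.m_stem - residual_stem_mass)
    harvested = cut_leaf + cut_stem
    harvested_n = cut_leaf * state.c_n("leaf", params) + cut_stem * state.c_n("stem", params)
    state.m_leaf -= cut_leaf
    state.m_stem -= cut_stem
    state.plant_n = max(0.0, state.plant_n - harvested_n)
    state.first_cut_done = True
    _translocate_storage(state, params)
    return harvested, harvested_n, state


def _translocate_storage(state: PlantState, params: PlantParams) -> None:
    """Move the whole storage pool into the other compartments according to
    the current allocation fractions (renormalized without storage)."""
    if state.m_storage <= 0:
        return
    theta = allocation_fractions(state, params)
    non_storage = theta["root"] + theta["leaf"] + theta["stem"]
    if non_storage <= 0:
        return
    pool = state.m_storage
    for x in ("root", "leaf", "stem"):
        state.set_mass(x, state.mass(x) + pool * theta[x] / non_storage)
    state.m_storage = 0.0


def season_transition(
    state: PlantState,
    daily_mean_t: float,
    doy: int,
    days_in_year: int,
    params: PlantParams,
    onset_threshold: float | None = None,
) -> tuple[PlantState, bool]:
    """Drive the annual season cycle.

    Degree days (base t_base) accumulate from Jan 1; when they reach the
    onset threshold the season starts and the storage pool is translocated
    to fuel spring growth.  On Dec 31 the seasonal counters (GDD, DVS,
    first-cut flag) reset.  Returns ``(state, season_started_today)``.
    """
    threshold = params.gdd_onset if onset_threshold is None else onset_threshold
    started = False
    state.annual_gdd += max(0.0, daily_mean_t - params.t_base)
    if not state.season_active and state.annual_gdd >= threshold:
        state.season_active = True
        started = True
        _translocate_storage(state, params)
    if doy == days_in_year:  # year-end reset
        state.gdd = 0.0
        state.annual_gdd = 0.0
        state.dvs = 0.0
        state.first_cut_done = False
        state.season_active = False
    return state, started
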