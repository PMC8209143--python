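"""Dynamic scheduling of cutting and manuring events.

Cuts are triggered on the fly whenever the simulated harvestable aboveground
biomass reaches a DOY-dependent *target biomass*; fallback rules force the
first cut at DOY 151 and subsequent cuts 56 days after the previous one if
the target is never reached.  Manure follows the cuts: the first application
at the simulated season start (never before Feb 1, never on snow or frozen
soil), the others on the first day without heavy rain (< 5 mm) within a
7-day window after each eligible cut, subject to an optional annual N cap.

Two target-biomass models are supported:

* *site-specific*: an ordinary least-squares line ``target = m * DOY + b``
  fitted to the per-event 75th percentile of observed harvests against DOY;
* *general*: per-cut-index fractions of the expected annual aboveground
  production, the latter given directly or estimated from site elevation by
  ``AGB [dt DM/ha/yr] = 159 - 0.058 h``.

All decision functions are pure: identical inputs give identical decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .soil import ManureComposition

__all__ = [
    "TargetBiomassModel",
    "ManagementRules",
    "ManagementEvent",
    "StaticSchedule",
    "fit_site_specific_target",
    "estimate_annual_yield_from_elevation",
    "target_biomass_for",
    "cut_decision",
    "manure_decision",
    "build_static_schedule",
    "configure_reduced_N",
    "schedule_cuts_from_trajectory",
    "DEFAULT_GENERAL_FRACTIONS",
]

# Shipped default per-cut fractions of annual aboveground production for a
# nominal 5-cut regime: linearly decreasing with cut index, summing to 1.
# A repo fixture (fitted shape, not a literature value).
DEFAULT_GENERAL_FRACTIONS = (0.30, 0.25, 0.20, 0.15, 0.10)


@dataclass(frozen=True)
class TargetBiomassModel:
    """DOY- and cut-index-dependent biomass threshold for scheduling cuts."""

    mode: str = "general"                       # "site_specific" | "general"
    slope: float = 0.0                          # kg DM/ha per DOY
    intercept: float = 0.0                      # kg DM/ha
    fractions: Sequence[float] = DEFAULT_GENERAL_FRACTIONS
    annual_agb: float = 10000.0                 # kg DM/ha/yr

    def __post_init__(self) -> None:
        if self.mode not in ("site_specific", "general"):
            raise ValueError(f"unknown target model mode {self.mode!r}")
        fr = np.asarray(self.fractions, dtype=float)
        if self.mode == "general":
            if np.any(fr <= 0):
                raise ValueError("general fractions must be positive")
            if np.any(np.diff(fr) > 1e-12):
                raise ValueError("general fractions must be non-increasing")
            if fr.sum() > 1.0 + 1e-6:
                raise ValueError("general fractions must sum to <= 1")

    @property
    def nominal_cuts(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class ManagementRules:
    """Thresholds and windows of the rule engine (days are DOY counts)."""

    first_cut_latest_doy: int = 150      # forced first cut on the day after
    max_days_between_cuts: int = 55      # forced cut on day 56 after previous
    manure_window_days: int = 7
    heavy_rain_threshold: float = 5.0    # mm/d
    earliest_manure_doy: int = 32        # Feb 1
    manure_after_cut_exclusions: frozenset = frozenset()
    exclude_after_final_nominal_cut: bool = True
    annual_n_cap: Optional[float] = None  # kg N/ha/yr
    season_end_doy: int = 305            # no cuts/manure after this DOY
    residual_leaf: float = 300.0         # kg DM/ha left standing at a cut
    residual_stem: float = 100.0

    def __post_init__(self) -> None:
        for name in ("first_cut_latest_doy", "max_days_between_cuts",
                     "manure_window_days", "earliest_manure_doy", "season_end_doy"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.heavy_rain_threshold < 0:
            raise ValueError("heavy_rain_threshold must be >= 0")
        if self.annual_n_cap is not None and self.annual_n_cap < 0:
            raise ValueError("annual_n_cap must be >= 0")

    @property
    def residual_total(self) -> float:
        return self.residual_leaf + self.residual_stem


@dataclass(frozen=True)
class ManagementEvent:
    """A dated cut or manure action, with the rule that triggered it."""

    date: object                 # pandas.Timestamp or datetime.date
    kind: str                    # "cut" | "manure"
    trigger: str                 # target_reached | doy_fallback | interval_fallback
    #                            # | static | season_start | post_cut
    harvest_dm: float = 0.0      # kg DM/ha (cuts)
    n_applied: float = 0.0       # kg N/ha (manure)
    c_applied: float = 0.0       # kg C/ha (manure)
    cut_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cut", "manure"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class StaticSchedule:
    """Fixed yearly calendar of cut and manure DOYs (experiment ii)."""

    cut_doys: Sequence[int]
    manure_doys: Sequence[int]
    composition: ManureComposition = field(default_factory=ManureComposition)

    def __post_init__(self) -> None:
        cuts = list(self.cut_doys)
        if sorted(cuts) != cuts or len(set(cuts)) != len(cuts):
            raise ValueError("cut DOYs must be sorted and distinct")
        if any(d < 1 or d > 365 for d in list(cuts) + list(self.manure_doys)):
            raise ValueError("schedule DOYs must lie within the year")

    @property
    def annual_n(self) -> float:
        return len(list(self.manure_doys)) * self.composition.n_load


def fit_site_specific_target(
    cut_records: Sequence[tuple[int, Sequence[float]]],
    percentile: float = 75.0,
    use_max: bool = False,
) -> tuple[float, float, float]:
    """Fit the site-specific target line to observed cut records.

    ``cut_records`` are ``(DOY, yields)`` groups, one per cutting event with
    replicate harvests (kg DM/ha).  Per event the 75th percentile (linear
    interpolation convention) of the replicates - or the maximum with
    ``use_max`` - is regressed on DOY by ordinary least squares.  Returns
    ``(slope, intercept, r2)``.
    """
    if len(cut_records) < 3:
        raise ValueError("need at least 3 cutting events to fit the target line")
    doys = np.array([float(d) for d, _ in cut_records])
    if np.allclose(doys, doys[0]):
        raise ValueError("degenerate fit: all events share one DOY")
    if use_max:
        y = np.array([np.max(v) for _, v in cut_records])
    else:
        y = np.array([np.percentile(np.asarray(v, dtype=float), percentile)
                      for _, v in cut_records])
    res = sps.linregress(doys, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def estimate_annual_yield_from_elevation(h: float) -> float:
    """Expected annual aboveground production (dt DM/ha/yr) of an
    intensively used (4-5 cuts) pre-alpine grassland at elevation ``h``
    (m a.s.l.): ``AGB = 159 - 0.058 h``.  Warns outside the 0-2000 m
    validity range."""
    if not 0.0 <= h <= 2000.0:
        warnings.warn(f"elevation {h} m outside the 0-2000 m validity range",
                      stacklevel=2)
    return 159.0 - 0.058 * h


def annual_yield_kg(h: float) -> float:
    """Elevation-based annual yield converted to kg DM/ha/yr."""
    return estimate_annual_yield_from_elevation(h) * 100.0


def target_biomass_for(model: TargetBiomassModel, doy: int, cut_index: int) -> float:
    """Target biomass (kg DM/ha) that triggers cut ``cut_index`` at ``doy``.

    Site-specific mode evaluates the fitted line regardless of cut index;
    general mode multiplies the per-cut fraction by the annual production,
    reusing the last fraction beyond the fitted range.
    """
    if cut_index < 1:
        raise ValueError("cut_index must be >= 1")
    if model.mode == "site_specific":
        return model.slope * doy + model.intercept
    fr = model.fractions
    frac = fr[min(cut_index, len(fr)) - 1]
    return frac * model.annual_agb


def cut_decision(
    today_doy: int,
    aboveground_biomass: float,
    last_cut_doy: Optional[int],
    cut_index: int,
    rules: ManagementRules,
    model: TargetBiomassModel,
) -> tuple[bool, Optional[str]]:
    """Decide whether to cut today (pure function; evaluated once per day).

    ``aboveground_biomass`` is the harvestable biomass (standing leaf + stem
    minus the configured residual); ``cut_index`` is the index this cut
    would have (1 for the first of the season).  Order of the rules: target
    reached, then first-cut-latest-DOY fallback, then inter-cut interval
    fallback.  No cuts after the season end.
    """
    if today_doy > rules.season_end_doy:
        return False, None
    if aboveground_biomass >= target_biomass_for(model, today_doy, cut_index):
        return True, "target_reached"
    # Fallbacks use ">=" so the rule still fires on the first evaluated day
    # when the season starts after the nominal fallback date.
    if cut_index == 1 and last_cut_doy is None:
        if today_doy >= rules.first_cut_latest_doy + 1:
            return True, "doy_fallback"
    elif last_cut_doy is not None:
        if today_doy - last_cut_doy >= rules.max_days_between_cuts + 1:
            return True, "interval_fallback"
    return False, None


def manure_decision(
    today_doy: int,
    window_open_doy: Optional[int],
    is_season_start_window: bool,
    snow_cover: bool,
    soil_frozen: bool,
    precip_today: float,
    rules: ManagementRules,
    annual_n_applied: float,
    composition: ManureComposition,
) -> tuple[bool, Optional[str]]:
    """Decide whether to apply slurry today (pure function).

    ``window_open_doy`` is the DOY the pending application window opened
    (season start or a cut); ``None`` means no application is pending.  The
    season-start application waits for bare, unfrozen ground and never
    happens before Feb 1 (DOY 32).  Post-cut applications wait for the first
    day with precipitation below the heavy-rain threshold within the window;
    if all window days are wet the search simply continues day by day (the
    caller aborts the window at the next cut or season end).  An application
    that would exceed the annual N cap is never scheduled.
    """
    if window_open_doy is None or today_doy > rules.season_end_doy:
        return False, None
    cap = rules.annual_n_cap
    if cap is not None and annual_n_applied + composition.n_load > cap + 1e-9:
        return False, None
    if is_season_start_window:
        if today_doy < max(window_open_doy, rules.earliest_manure_doy):
            return False, None
        if snow_cover or soil_frozen:
            return False, None
        return True, "season_start"
    if today_doy <= window_open_doy:
        return False, None  # window opens the day after the cut
    if precip_today >= rules.heavy_rain_threshold:
        return False, None
    if snow_cover or soil_frozen:
        return False, None
    return True, "post_cut"


def build_static_schedule(
    mean_cut_doys: Sequence[int],
    mean_manure_doys: Sequence[int],
    composition: ManureComposition | None = None,
) -> StaticSchedule:
    """Yearly event template from mean historical cut and manure DOYs; the
    same calendar (by DOY) applies to every simulated year."""
    comp = composition if composition is not None else ManureComposition()
    return StaticSchedule(tuple(mean_cut_doys), tuple(mean_manure_doys), comp)


@dataclass(frozen=True)
class ReducedNPolicy:
    """Manure policy of the reduced-fertilization scenario: applications
    only at season start and after the first and third cut, loads scaled so
    the annual total respects the cap."""

    composition: ManureComposition
    cap: float
    allowed_slots: frozenset = frozenset({0, 1, 3})  # 0 = season start

    @property
    def annual_n(self) -> float:
        return len(self.allowed_slots) * self.composition.n_load


def configure_reduced_N(
    composition: ManureComposition,
    cap: float = 170.0,
) -> ReducedNPolicy:
    """Restrict manuring to the three legal slots and scale per-event loads
    so the annual total stays at or below ``cap`` kg N/ha/yr."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    slots = frozenset({0, 1, 3})
    if cap == 0:
        return ReducedNPolicy(composition.scaled(0.0), cap, frozenset())
    total = len(slots) * composition.n_load
    factor = min(1.0, cap / total) if total > 0 else 1.0
    return ReducedNPolicy(composition.scaled(factor), cap, slots)


def schedule_cuts_from_trajectory(
    biomass_by_doy: Sequence[float],
    rules: ManagementRules,
    model: TargetBiomassModel,
    season_start_doy: int = 1,
) -> list[tuple[int, str]]:
    """Run the cut rule engine over a prescribed harvestable-biomass
    trajectory (index 0 = DOY 1).  Used by the ``schedule`` CLI verb and as
    the production side of the rule-compliance checks.  Returns
    ``(doy, trigger)`` pairs."""
    events: list[tuple[int, str]] = []
    last_cut: Optional[int] = None
    cut_index = 1
    for i, biomass in enumerate(biomass_by_doy):
        doy = i + 1
        if doy < season_start_doy:
            continue
        do_cut, trigger = cut_decision(doy, float(biomass), last_cut, cut_index,
                                       rules, model)
        if do_cut:
            events.append((doy, trigger))
            last_cut = doy
            cut_index += 1
    return events
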