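"""Daily weather series: stochastic generation, scenario perturbation, and
hourly disaggregation.

The simulator is forced by daily minimum/maximum air temperature (degC),
precipitation (mm/d) and daily-mean global radiation (W/m2).  Series are held
as :class:`pandas.DataFrame` objects with columns ``date, tmin, tmax, precip,
rad``; :class:`WeatherDay` is the single-day view used in the daily loop.

The built-in generator is a standard parametric weather generator: first-order
two-state Markov chain for precipitation occurrence, gamma-distributed wet-day
amounts, AR(1) residuals around monthly temperature normals, and radiation
drawn conditionally on the wet/dry state.  Climate-change scenarios are
applied as monthly additive temperature deltas and multiplicative
precipitation factors, optionally interpolated in time between anchor years,
plus a piecewise-linear CO2 pathway.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

WEATHER_COLUMNS = ["date", "tmin", "tmax", "precip", "rad"]

__all__ = [
    "WeatherDay",
    "WeatherHour",
    "GeneratorStats",
    "ScenarioSpec",
    "generate_daily_weather",
    "apply_climate_deltas",
    "bias_correct_temperature",
    "co2_at",
    "disaggregate_to_hourly",
    "diurnal_temperature_cycle",
    "solar_radiation_cycle",
    "day_length_hours",
    "read_weather_csv",
    "write_weather_csv",
]


class WeatherDay(NamedTuple):
    """One day of model forcing."""

    date: pd.Timestamp
    tmin: float
    tmax: float
    precip: float
    rad: float

    def validate(self) -> "WeatherDay":
        if self.tmin > self.tmax + 1e-9:
            raise ValueError(f"tmin {self.tmin} > tmax {self.tmax} on {self.date}")
        if self.precip < 0:
            raise ValueError(f"negative precip on {self.date}")
        if self.rad < 0:
            raise ValueError(f"negative radiation on {self.date}")
        return self

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmin + self.tmax)


class WeatherHour(NamedTuple):
    """One hour of disaggregated forcing (hour index 0-23)."""

    hour: int
    temperature: float
    precip: float
    radiation: float


def _month_vec(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"{name} must have 12 monthly entries, got shape {arr.shape}")
    return arr


@dataclass
class GeneratorStats:
    """Per-month target statistics for the stochastic weather generator.

    ``p_wet`` is the unconditional wet-day probability, ``p_wet_wet`` the
    wet-after-wet persistence; the wet-after-dry probability follows from
    stationarity.  Wet-day precipitation amounts are gamma distributed with
    the given mean and a common shape parameter.
    """

    tmin_mean: Sequence[float]
    tmin_sd: Sequence[float]
    tmax_mean: Sequence[float]
    tmax_sd: Sequence[float]
    p_wet: Sequence[float]
    p_wet_wet: Sequence[float]
    precip_wet_mean: Sequence[float]
    rad_mean_dry: Sequence[float]
    rad_sd_dry: Sequence[float]
    rad_mean_wet: Sequence[float]
    rad_sd_wet: Sequence[float]
    precip_shape: float = 0.75
    temp_autocorr: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "tmin_mean", "tmin_sd", "tmax_mean", "tmax_sd", "p_wet", "p_wet_wet",
            "precip_wet_mean", "rad_mean_dry", "rad_sd_dry", "rad_mean_wet",
            "rad_sd_wet",
        ):
            setattr(self, name, _month_vec(getattr(self, name), name))
        self.validate()

    def validate(self) -> None:
        for name in ("tmin_sd", "tmax_sd", "rad_sd_dry", "rad_sd_wet"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains a negative SD")
        for name in ("p_wet", "p_wet_wet"):
            p = getattr(self, name)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.precip_wet_mean < 0):
            raise ValueError("negative wet-day precipitation mean")
        if np.any(self.tmin_mean > self.tmax_mean):
            raise ValueError("monthly tmin mean exceeds tmax mean")
        if self.precip_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if not 0 <= self.temp_autocorr < 1:
            raise ValueError("temperature autocorrelation must be in [0, 1)")

    def p_wet_dry(self) -> np.ndarray:
        """Wet-after-dry probability implied by stationary wet frequency."""
        p, pww = self.p_wet, self.p_wet_wet
        with np.errstate(divide="ignore", invalid="ignore"):
            pwd = np.where(p < 1.0, p * (1.0 - pww) / (1.0 - p), 1.0)
        return np.clip(pwd, 0.0, 1.0)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorStats":
        kwargs = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        return cls(**kwargs)


@dataclass
class ScenarioSpec:
    """Climate-change scenario: monthly deltas plus a CO2 pathway.

    ``anchors`` maps an anchor year to ``(temp_delta[12], precip_factor[12])``;
    between anchor years the deltas are interpolated linearly in time.  A
    single anchor means time-constant deltas.  ``co2_anchors`` maps year to
    ppm for piecewise-linear interpolation.
    """

    label: str = "baseline"
    anchors: dict = field(default_factory=dict)
    co2_anchors: dict = field(default_factory=lambda: {2011: 400.0, 2100: 400.0})

    def __post_init__(self) -> None:
        norm = {}
        for year, (dt, pf) in sorted(self.anchors.items()):
            dt = np.broadcast_to(np.asarray(dt, dtype=float), (12,)).copy()
            pf = np.broadcast_to(np.asarray(pf, dtype=float), (12,)).copy()
            if np.any(pf <= 0):
                raise ValueError("precipitation factors must be > 0")
            norm[int(year)] = (dt, pf)
        self.anchors = norm
        years = sorted(self.co2_anchors)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("CO2 pathway years must be strictly increasing")
        self.co2_anchors = {int(y): float(self.co2_anchors[y]) for y in years}

    def deltas_at(self, dec_year: float) -> tuple[np.ndarray, np.ndarray]:
        """Monthly (temp delta, precip factor) at a decimal year."""
        if not self.anchors:
            return np.zeros(12), np.ones(12)
        years = np.array(sorted(self.anchors), dtype=float)
        dts = np.stack([self.anchors[int(y)][0] for y in years])
        pfs = np.stack([self.anchors[int(y)][1] for y in years])
        dt = np.array([np.interp(dec_year, years, dts[:, m]) for m in range(12)])
        pf = np.array([np.interp(dec_year, years, pfs[:, m]) for m in range(12)])
        return dt, pf


def generate_daily_weather(
    stats: GeneratorStats,
    years: int,
    seed: int,
    start_year: int = 2011,
) -> pd.DataFrame:
    """Generate a daily weather series for ``years`` calendar years.

    Reproducible for identical ``seed``; per-month long-run means converge to
    the configured normals as the series grows.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    stats.validate()
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D")
    n = len(dates)
    month = dates.month.to_numpy() - 1

    rho = stats.temp_autocorr
    innov_scale = np.sqrt(1.0 - rho * rho)
    z_max = rng.standard_normal(n)
    z_min = rng.standard_normal(n)
    u_wet = rng.random(n)
    # Standardized AR(1) residual shared structure: tmax carries the chain,
    # tmin correlates with it (r = 0.8) plus its own noise.
    e = np.empty(n)
    prev = 0.0
    for i in range(n):
        prev = rho * prev + innov_scale * z_max[i]
        e[i] = prev
    r_cross = 0.8
    e_min = r_cross * e + np.sqrt(1.0 - r_cross**2) * z_min

    tmax = stats.tmax_mean[month] + stats.tmax_sd[month] * e
    tmin = stats.tmin_mean[month] + stats.tmin_sd[month] * e_min
    tmin = np.minimum(tmin, tmax)

    pwd = stats.p_wet_dry()
    wet = np.zeros(n, dtype=bool)
    prev_wet = False
    for i in range(n):
        p = stats.p_wet_wet[month[i]] if prev_wet else pwd[month[i]]
        prev_wet = u_wet[i] < p
        wet[i] = prev_wet

    precip = np.zeros(n)
    n_wet = int(wet.sum())
    if n_wet:
        shape = stats.precip_shape
        scale = stats.precip_wet_mean[month[wet]] / shape
        precip[wet] = rng.gamma(shape, scale, size=n_wet)

    rad_mean = np.where(wet, stats.rad_mean_wet[month], stats.rad_mean_dry[month])
    rad_sd = np.where(wet, stats.rad_sd_wet[month], stats.rad_sd_dry[month])
    rad = np.clip(rad_mean + rad_sd * rng.standard_normal(n), 0.0, None)

    return pd.DataFrame(
        {"date": dates, "tmin": tmin, "tmax": tmax, "precip": precip, "rad": rad}
    )


def apply_climate_deltas(series: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Shift temperatures and scale precipitation by the scenario's monthly,
    time-interpolated deltas.  ``tmin <= tmax`` is preserved (both shift by
    the same delta)."""
    if len(series) == 0:
        raise ValueError("empty weather series")
    out = series.copy()
    dates = pd.DatetimeIndex(out["date"])
    month = dates.month.to_numpy() - 1
    year = dates.year.to_numpy()
    doy = dates.dayofyear.to_numpy()
    ndays = np.where(dates.is_leap_year, 366, 365)
    dec_year = year + (doy - 1) / ndays

    if spec.anchors:
        anchor_years = np.array(sorted(spec.anchors), dtype=float)
        dts = np.stack([spec.anchors[int(y)][0] for y in anchor_years])
        pfs = np.stack([spec.anchors[int(y)][1] for y in anchor_years])
        dt_day = np.empty(len(out))
        pf_day = np.empty(len(out))
        for m in range(12):
            sel = month == m
            if not sel.any():
                continue
            dt_day[sel] = np.interp(dec_year[sel], anchor_years, dts[:, m])
            pf_day[sel] = np.interp(dec_year[sel], anchor_years, pfs[:, m])
        out["tmin"] = out["tmin"] + dt_day
        out["tmax"] = out["tmax"] + dt_day
        out["precip"] = out["precip"] * pf_day
    return out


def bias_correct_temperature(
    series: pd.DataFrame,
    slope: float,
    intercept: float,
    fields: Iterable[str] = ("tmin", "tmax"),
) -> pd.DataFrame:
    """Linear bias correction ``t -> slope * t + intercept`` on the chosen
    temperature columns (used to transfer a nearby station's record to a
    site, e.g. valley stations with systematic offsets)."""
    out = series.copy()
    for f in fields:
        out[f] = slope * out[f] + intercept
    return out


def co2_at(year: float, spec: ScenarioSpec) -> float:
    """Atmospheric CO2 (ppm) at ``year`` by piecewise-linear interpolation of
    the scenario's pathway anchors.  Raises outside the anchored range."""
    years = np.array(sorted(spec.co2_anchors), dtype=float)
    if year < years[0] or year > years[-1]:
        raise ValueError(f"year {year} outside CO2 pathway range [{years[0]}, {years[-1]}]")
    ppm = np.array([spec.co2_anchors[int(y)] for y in years])
    return float(np.interp(year, years, ppm))


def day_length_hours(day_of_year: int, latitude: float) -> float:
    """Astronomical day length from solar declination and latitude."""
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (day_of_year + 10) / 365.25)
    lat = np.deg2rad(latitude)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    return float(24.0 * np.arccos(cos_ws) / np.pi)


# Diurnal temperature curve: pure 24-h cosine with the minimum at 04:00
# (near sunrise in the growing season) and the maximum at 16:00.  Evaluated
# on integer hours the cosine sums to exactly zero, so the 24-h mean equals
# (tmin + tmax) / 2 and the min/max are hit exactly.
_T_MIN_HOUR = 4
_HOURS = np.arange(24)
_COS = -np.cos(2.0 * np.pi * (_HOURS - _T_MIN_HOUR) / 24.0)


def diurnal_temperature_cycle(tmin: float, tmax: float) -> np.ndarray:
    """24 hourly temperatures with exact min/max and mean (tmin+tmax)/2."""
    mid = 0.5 * (tmin + tmax)
    amp = 0.5 * (tmax - tmin)
    return mid + amp * _COS


def solar_radiation_cycle(rad_daily_mean: float, day_of_year: int, latitude: float) -> np.ndarray:
    """24 hourly global-radiation values (W/m2): half-sine over daylight,
    zero at night, rescaled so the 24-h mean equals the daily mean."""
    if rad_daily_mean <= 0:
        return np.zeros(24)
    dl = day_length_hours(day_of_year, latitude)
    if dl <= 0:
        # polar night guard: spread uniformly
        return np.full(24, rad_daily_mean)
    sunrise = 12.0 - dl / 2.0
    # evaluate at hour centres h + 0.5
    x = (_HOURS + 0.5 - sunrise) / dl
    shape = np.where((x > 0) & (x < 1), np.sin(np.pi * np.clip(x, 0, 1)), 0.0)
    total = shape.sum()
    if total <= 0:
        return np.full(24, rad_daily_mean)
    return shape * (rad_daily_mean * 24.0 / total)


def disaggregate_to_hourly(
    day: WeatherDay, day_of_year: int, latitude: float
) -> list[WeatherHour]:
    """Disaggregate one day to 24 :class:`WeatherHour` records.

    Hourly temperatures span exactly [tmin, tmax]; precipitation is spread
    uniformly (sum preserved exactly); radiation follows a day-length
    dependent half-sine whose 24-h mean equals the daily mean.
    """
    temp = diurnal_temperature_cycle(day.tmin, day.tmax)
    rad = solar_radiation_cycle(day.rad, day_of_year, latitude)
    p = day.precip / 24.0
    return [WeatherHour(h, float(temp[h]), p, float(rad[h])) for h in range(24)]


def read_weather_csv(path) -> pd.DataFrame:
    """Read a ``date,tmin,tmax,precip,rad`` CSV and validate invariants."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather CSV missing columns: {missing}")
    df = df[WEATHER_COLUMNS]
    if (df["tmin"] > df["tmax"] + 1e-9).any():
        bad = df.loc[df["tmin"] > df["tmax"] + 1e-9, "date"].iloc[0]
        raise ValueError(f"tmin > tmax on {bad}")
    if (df["precip"] < 0).any() or (df["rad"] < 0).any():
        raise ValueError("negative precipitation or radiation in weather CSV")
    return df.reset_index(drop=True)


def write_weather_csv(series: pd.DataFrame, path) -> None:
    out = series[WEATHER_COLUMNS].copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def iter_weather_days(series: pd.DataFrame):
    """Iterate a series as validated :class:`WeatherDay` tuples."""
    for row in series.itertuples(index=False):
        yield WeatherDay(row.date, row.tmin, row.tmax, row.precip, row.rad)
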