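"""Deterministic synthetic test inputs.

Everything here is generated, seeded and small: a weather year exercising
the CSV reader, replicated cut records emulating a multi-year harvest
campaign (22 events, 3 replicates each), a phenology-network-like table of
first-cut DOYs with a warming trend, and a writable soil profile.  These are
synthetic stand-ins for field observations, used by tests and examples.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfg
from . import weather as wx

__all__ = ["generate_fixtures", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("weather_year", "cut_records", "dwd_like_phenology", "soil_profiles")


def generate_fixtures(kind: str, seed: int, outdir: str | Path | None = None):
    """Build one fixture kind; optionally write it under ``outdir``.

    Returns the in-memory object (DataFrame, list, or dict)."""
    if kind == "weather_year":
        df = wx.generate_daily_weather(cfg.default_generator_stats(), 1, seed)
        if outdir:
            wx.write_weather_csv(df, Path(outdir) / "weather_year.csv")
        return df

    if kind == "cut_records":
        # 22 cutting events with 3 replicate harvests each, spread over
        # multiple seasons; replicate yields scatter around a linear
        # DOY-dependent standing biomass.
        rng = np.random.default_rng(seed)
        true_slope, true_intercept = 10.0, 1200.0
        records = []
        doys = rng.integers(120, 290, size=22)
        for doy in sorted(int(d) for d in doys):
            mu = true_slope * doy + true_intercept
            reps = mu + rng.normal(0.0, 250.0, size=3)
            records.append((doy, [float(max(r, 100.0)) for r in reps]))
        if outdir:
            rows = [{"doy": d, "rep": i + 1, "yield_kg_dm_ha": y}
                    for d, ys in records for i, y in enumerate(ys)]
            pd.DataFrame(rows).to_csv(Path(outdir) / "cut_records.csv", index=False)
        return records

    if kind == "dwd_like_phenology":
        # 26 years of first-cut DOY and mean annual temperature with a
        # warming trend and an earlier-cut response, phenology-network style.
        rng = np.random.default_rng(seed)
        years = np.arange(1991, 2017)
        mat = 7.5 + 0.025 * (years - years[0]) + rng.normal(0, 0.4, len(years))
        doy = 155 - 10.0 * (mat - mat.mean()) + rng.normal(0, 5, len(years))
        df = pd.DataFrame({"year": years, "mat_degc": mat,
                           "first_cut_doy": np.round(doy).astype(int)})
        if outdir:
            df.to_csv(Path(outdir) / "phenology.csv", index=False)
        return df

    if kind == "soil_profiles":
        profile = cfg.default_soil_profile()
        data = {"horizons": [
            {"upper_cm": h.upper_cm, "lower_cm": h.lower_cm,
             "bulk_density": h.bulk_density, "ph": h.ph, "c_org": h.c_org,
             "n_org": h.n_org, "clay": h.clay, "silt": h.silt, "sand": h.sand,
             "field_capacity": h.field_capacity, "wilting_point": h.wilting_point,
             "hydraulic_conductivity": h.hydraulic_conductivity,
             "stone_fraction": h.stone_fraction}
            for h in profile.horizons]}
        if outdir:
            import yaml
            with open(Path(outdir) / "soil_profile.yaml", "w") as fh:
                yaml.safe_dump(data, fh)
        return data

    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
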