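"""Contrast static, dynamic and reduced-N management on identical weather.

Runs 30 years of strong-warming forcing through all three management modes
and prints period-mean yields, cut counts and fertilizer loads.  Dynamic
management tracks the shifting season; the reduced-N policy caps slurry at
three slots per year.
"""

from dynagrass import config as cfg
from dynagrass.simulate import SimulationConfig, compare_managements

base = SimulationConfig(mode="dynamic", years=30, seed=1, start_year=2071,
                        scenario=cfg.default_scenario("strong"))
df = compare_managements({
    "dynamic": base,
    "static": base.replace(mode="static"),
    "reduced": base.replace(mode="dynamic_reduced_n"),
})

for label in ("dynamic", "static", "reduced"):
    print(f"{label:8s} harvest {df[f'harvest_{label}'].mean():7.0f} kg DM/ha/yr, "
          f"cuts {df[f'cuts_{label}'].mean():.1f}/yr, "
          f"N {df[f'n_applied_{label}'].mean():5.0f} kg/ha/yr")
print("\nmean yearly advantage of dynamic over static: "
      f"{df['harvest_diff_static_vs_dynamic'].mean() * -1:.0f} kg DM/ha")
# Positive advantage: the on-the-fly scheduler converts the longer warm
# season into extra cuts and fertilizer events that a fixed calendar misses.
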