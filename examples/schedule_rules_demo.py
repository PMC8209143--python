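"""Exercise the cut rule engine on a toy biomass trajectory.

Builds the general elevation-based target model for an 864 m site and
drives the daily cut decision with a simple regrow-and-reset sward,
showing how the target rule and the DOY-151 / 56-day fallbacks interact.
"""

from dynagrass.management import (
    ManagementRules,
    TargetBiomassModel,
    annual_yield_kg,
    target_biomass_for,
)

agb = annual_yield_kg(864.0)
model = TargetBiomassModel(mode="general", annual_agb=agb)
print(f"expected annual yield at 864 m: {agb:.1f} kg DM/ha")
for i in range(1, 6):
    print(f"  cut {i} target: {target_biomass_for(model, 150, i):.0f} kg DM/ha")

# drive the daily decision with a toy sward that regrows at 45 kg/d and is
# reset by each scheduled cut (the full simulator supplies this feedback
# from the growth model)
from dynagrass.management import cut_decision  # noqa: E402

rules = ManagementRules()
biomass, last_cut, index = 0.0, None, 1
print("\nscheduled cuts (DOY, trigger, standing biomass):")
for doy in range(90, 306):
    biomass += 45.0
    cut, trigger = cut_decision(doy, biomass, last_cut, index, rules, model)
    if cut:
        print(f"  {doy:3d}  {trigger:18s} {biomass:6.0f} kg DM/ha")
        biomass, last_cut, index = 0.0, doy, index + 1
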