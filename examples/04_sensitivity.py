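"""Precipitation sensitivity of a six-year-old tree.

Scales every day's rainfall from 50% to 150% of the reference, re-simulates
the whole six-cycle trajectory and prints the percent change of the final
tree relative to the unscaled run.
"""

from pinewater import BranchingRules, PlantParams, SiteInfo, SoilParams
from pinewater.sensitivity import precipitation_sweep, ratio_track
from pinewater.synthetic import synth_weather_years

result = precipitation_sweep(
    synth_weather_years(seed=1), SoilParams(), SiteInfo(),
    BranchingRules(), PlantParams(), seed=0,
)
cols = ["scale", "aboveground", "trunk_mass", "height", "basal_diameter"]
print(result.changes[cols].round(2).to_string(index=False))

track, crossing = ratio_track(result)
print()
print(f"internode:needle ratio spans "
      f"{track['internode_needle_ratio'].min():.2f}.."
      f"{track['internode_needle_ratio'].max():.2f}; "
      f"dominance crossing: {crossing}")
print("biomass responds roughly linearly and far more strongly than height")
print("or diameter, whose allometric exponents damp the water signal.")
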