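"""One growth season of the root-zone water balance.

Generates a synthetic 412.6 mm weather year, runs the daily depletion
bookkeeping for a canopy of LAI 0.5 and prints the season totals: ETa is
the water the stand evaporates and transpires, Ta the canopy-transpired
share that drives biomass production.
"""

from pinewater import SiteInfo, SoilParams, run_season
from pinewater.synthetic import synth_weather, weather_spec_for_year

site = SiteInfo()
soil = SoilParams()
year = synth_weather(weather_spec_for_year(2007, seed=1))

season = run_season(year, soil, lai=0.5, site=site)
print(f"growth season: days {season.start}..{season.end} of the year")
print(f"precipitation in season : {season.precip_total:7.1f} mm")
print(f"actual evapotranspiration: {season.et_a_total:7.1f} mm")
print(f"plant transpiration      : {season.t_a_total:7.1f} mm")
print(f"final root-zone depletion: {season.d_r_final:7.1f} mm (of TAW {soil.taw:.0f} mm)")
print()
print("ETa tracks rainfall plus the 50 mm the root zone stores; the canopy")
print("fraction 1-exp(-k*LAI) decides how much of it the tree transpires.")
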