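"""Generate one synthetic country and look at what it contains.

A country bundle is a stack of covariate grids, a nearest-seed admin
zonation, a census table derived by integrating the planted density
surface, and the true log-density grid itself.
"""

import numpy as np

import dasypop as dp

spec = dp.demo_study_spec(seed=1)
country = dp.generate_country(spec, region_label="region-1",
                              country_label="demo")

print(f"grid: {spec.grid_rows}x{spec.grid_cols} pixels "
      f"({spec.grid_rows * spec.grid_cols * spec.pixel_area:.0f} km2)")
print(f"admin units: {len(country.census)}, "
      f"ASR = {country.asr_km:.2f} km")
print(f"total population: {country.census['count'].sum()}")
print(f"people per unit: median {country.census['count'].median():.0f}, "
      f"max {country.census['count'].max()}")
zero = (country.census["count"] == 0).sum()
print(f"zero-count units: {zero}")
dens = np.exp(country.true_log_density)
print(f"true density range: {dens.min():.1f} - {dens.max():.0f} "
      f"people/km2")
# ASR is sqrt(mean unit area): the scalar 'census granularity' of the
# country; population totals are exact integrals of the density surface.
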