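"""Profile one simulated EcoPlate incubation.

Simulates a 100-day dual-wavelength plate read every 24 h, applies the
turbidity and control correction, and prints the sample's metabolic
statistics: the AWCD level reached, how many of the 31 substrates were
oxidized (richness), the functional-diversity indices computed from the
substrate color-development profile, and when the community entered its
exponential and stable growth phases.
"""

from clpp import PlateSimConfig, correct_series, profile, simulate_plate

config = PlateSimConfig(seed=3)
layout, readings = simulate_plate(config, sample_profile=1.0, sample_id="surface_water")
series = correct_series(readings, layout)

p = profile(series)
print(f"sample:            {p.sample_id}")
print(f"reference time:    {p.reference_time_h:.0f} h "
      f"({p.reference_time_h / 24:.0f} days, stable-phase onset)")
print(f"AWCD at reference: {p.awcd_series.loc[p.reference_time_h]:.3f}")
print(f"richness:          {p.richness_r} of 31 substrates oxidized (OD >= 0.5, "
      "two consecutive reads)")
print(f"Simpson D:         {p.simpson_d:.3f}   (log form -ln sum Pi^2; ln 31 = 3.434 at uniform use)")
print(f"Shannon H:         {p.shannon_h:.3f}   (max ln 31 = 3.434)")
print(f"exponential phase from {p.phase.t_exp_start:.0f} h, "
      f"stable phase from {p.phase.t_stable_start:.0f} h")
print("\nper-category AWCD at the reference time:")
for cat, val in p.awcd_by_category[p.reference_time_h].sort_values(ascending=False).items():
    print(f"  {cat:<15} {val:.3f}")
print("\nHigh Shannon/Simpson close to ln 31 mean this simulated community "
      "developed color on nearly all substrates at comparable levels.")
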