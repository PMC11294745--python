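"""Simulate a minibeam dose plane and inspect its comb structure.

A 150 MeV field is scanned uniformly across a 5-slit brass collimator
(0.4 mm slits, 2.8 mm centre-to-centre) with a 6 cm air gap, and the dose
is scored in water on a 0.1 mm x 0.5 mm grid.
"""

import numpy as np

import pmbrt as pm

beam = pm.BeamSpec(energy=150.0, mu_scale=8.0)
collimator = pm.CollimatorSpec(n_slits=5, slit_width=0.4, ctc=2.8)
grid_spec = pm.PhantomGridSpec(x_extent=60.0, z_extent=170.0, air_gap=60.0)

grid = pm.minibeam_dose(beam, collimator, grid_spec)
print(f"field size: {pm.collimator_extent(collimator)} cm "
      f"(lateral extent of the 5-slit comb)")
print(f"proton range: {beam.range_mm:.1f} mm in water")

profile = grid.lateral_profile(10.0)
pv = pm.find_peaks_valleys(profile, collimator.ctc)
print(f"at 1 cm depth: {pv.n_peaks} peaks, {len(pv.valley_x)} valleys, "
      f"peak spacing {np.mean(np.diff(pv.peak_x)):.2f} mm")

curve = pm.pvdr_vs_depth(grid, collimator, np.arange(10.0, 101.0, 10.0))
print("\ndepth_cm  pvdr   (peak column at "
      f"x = {curve.meta['peak_column_mm']:.1f} mm)")
for z, v in zip(curve.z, curve.pvdr):
    print(f"{z / 10.0:7.0f}  {v:5.2f}")
print("\nThe PVDR starts high where the beamlets are distinct and decays "
      "to 1 as multiple\nCoulomb scattering merges the combs near the end "
      "of range.")
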