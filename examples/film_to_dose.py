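"""Film chain: expose, scan, and convert back to dose.

A minibeam plane is rendered as a 48-bit RGB film scan at 300 dpi through
the channel calibrations, then inverted with the single-channel and the
disturbance-cancelling multichannel methods.
"""

import numpy as np

import pmbrt as pm

beam = pm.BeamSpec(energy=150.0, mu_scale=8.0)
collimator = pm.CollimatorSpec()
grid = pm.minibeam_dose(
    beam, collimator, pm.PhantomGridSpec(x_extent=60.0, z_extent=60.0, air_gap=60.0)
)
cals = pm.default_calibration_triple()

# a 2% film-thickness disturbance perturbs all three channels coherently
scan = pm.film_digitize(grid, cal=cals, noise_sd=0.0, seed=0, disturbance=1.02)
print(f"scan: {scan.pixels.shape[1]} x {scan.pixels.shape[0]} px at "
      f"{scan.dpi:.0f} dpi ({scan.pixel_pitch:.4f} mm/px)")

single = pm.to_dose(scan, cals[0], method="single_channel")
multi = pm.to_dose(scan, cals, method="multichannel")

profile_s = pm.extract_lateral_profile(single, depth=10.0, band_px=3)
profile_m = pm.extract_lateral_profile(multi, depth=10.0, band_px=3)
truth = grid.lateral_profile(10.0)

peak_true = truth.dose.max()
print(f"\npeak dose at 1 cm:   truth {peak_true:.2f} Gy")
print(f"  single channel:    {profile_s.dose.max():.2f} Gy "
      f"({100 * (profile_s.dose.max() / peak_true - 1):+.1f}%)")
print(f"  multichannel:      {profile_m.dose.max():.2f} Gy "
      f"({100 * (profile_m.dose.max() / peak_true - 1):+.1f}%)")
print(f"  estimated disturbance: "
      f"{100 * np.median(multi.meta['disturbance']):.1f}% (injected 2.0%)")
print("\nThe multichannel solve cancels the thickness-like disturbance that "
      "biases any\nsingle-channel inversion.")
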