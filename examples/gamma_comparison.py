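"""1D gamma comparison of two lateral profiles, with the brute-force oracle.

The gamma index combines a 3% dose difference with a 0.1 mm
distance-to-agreement; a point passes when gamma <= 1.  The ROI covers the
comb plus 2 mm beyond the outermost peaks, with no low-dose cut-off.
"""

import numpy as np

import pmbrt as pm
from pmbrt.engine import _comb_factor, lateral_sigma

beam = pm.BeamSpec(energy=150.0, mu_scale=8.0)
col = pm.CollimatorSpec()
sig = float(lateral_sigma(beam, 10.0, 60.0, exit_sigma=col.exit_sigma,
                          exit_theta=col.exit_theta))

x_ref = np.arange(-12.0, 12.0001, 0.1)   # detector-like 0.1 mm scan steps
x_fine = np.arange(-12.0, 12.0001, 0.02)


def comb(x):
    return 8.0 * (_comb_factor(x, sig, col.slit_centers, col.slit_widths,
                               np.ones(5)) + col.leakage)


ref = pm.Profile1D(x_ref, comb(x_ref), depth_tag=10.0)
shifted = pm.Profile1D(x_fine, comb(x_fine - 0.15), depth_tag=10.0)

for dta in (0.1, 0.2):
    crit = pm.GammaCriteria(dose_tol=0.03, dta=dta)
    res = pm.gamma_1d(ref, shifted, crit)
    oracle = pm.gamma_oracle(ref, shifted, crit)
    dev = np.abs(res.gamma - oracle.gamma).max()
    print(f"3%/{dta} mm: pass rate {100 * res.pass_rate:5.1f}% over "
          f"{res.n_points} points in ROI [{res.roi[0]:.1f}, {res.roi[1]:.1f}] mm"
          f"  (|engine - oracle| < {dev:.1e})")

print("\nA 0.15 mm lateral shift fails much of the comb at 0.1 mm DTA but "
      "passes at 0.2 mm —\nthe criteria must resolve the sub-millimetre dose "
      "gradients.")
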