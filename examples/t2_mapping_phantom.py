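"""Rician-MLE T2 mapping of a lesioned heart phantom.

Builds a three-slice annulus phantom with one focal high-T2 lesion,
estimates the noise scale from the image background, fits a pixel-wise T2
map under the Rician likelihood, and compares it with the log-linear
least-squares fit.
"""

import numpy as np

from cmrmulti.synthetic import Lesion, PhantomSpec, simulate_heart_phantom
from cmrmulti.t2map import estimate_sigma, fit_map

phantom = simulate_heart_phantom(
    PhantomSpec(
        grid_size=96,
        r_endo=16.0,
        r_epi=28.0,
        base_t2=55.0,
        lesions=(Lesion(center_angle_deg=30, extent_deg=60, transmural_fraction=0.6,
                        delta_t2=20.0, t2_spread=4.0, level="basal"),),
        sigma=20.0,
        seed=1,
    )
)

rows, cols = np.indices((96, 96))
background = np.hypot(rows - 47.5, cols - 47.5) > 36
sigma = estimate_sigma(phantom.stack, background)
print(f"noise scale per slice (true 20.0): {np.round(sigma, 2)}")

mle_map = fit_map(phantom.stack, phantom.mask, method="rician_mle", sigma=sigma)
ll_map = fit_map(phantom.stack, phantom.mask, method="loglinear")

truth = phantom.t2_truth[phantom.mask]
for name, fitted in (("Rician MLE", mle_map), ("log-linear", ll_map)):
    err = fitted.t2[phantom.mask] - truth
    print(f"{name:11s}: mean error {np.nanmean(err):+.2f} ms, "
          f"RMS error {np.sqrt(np.nanmean(err**2)):.2f} ms")

# The MLE mean error should sit closer to zero: the log-linear fit inherits
# the upward Rician noise-floor bias at the long echo times.
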