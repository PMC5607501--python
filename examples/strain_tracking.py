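"""Feature-tracking strain on a contracting cine phantom.

Renders a ring phantom whose perimeter follows a prescribed -25% peak
strain curve, tracks the end-diastolic contour by block matching, and
compares the recovered peak circumferential strain and strain rate with
the planted truth.
"""

import numpy as np

from cmrmulti.synthetic import CineSpec, circle_contour, simulate_cine
from cmrmulti.tracking import peak_value, strain_from_contour, track_contour

n_frames, peak = 20, -25.0
t = np.arange(n_frames) / n_frames
eps = peak * np.sin(np.pi * t) ** 2
eps[0] = 0.0

cine = simulate_cine(
    CineSpec(
        n_frames=n_frames,
        contour=circle_contour((64.0, 64.0), 26.0, 48),
        strain_curve=tuple(eps),
        noise_sd=2.0,
        seed=7,
    )
)
tracked = track_contour(cine.frames, cine.contours[0], frame_times=cine.frame_times)
curve = strain_from_contour(tracked, kind="circumferential", chamber="LV")

print(f"planted peak strain : {peak:+.1f} %")
print(f"tracked peak strain : {peak_value(curve.epsilon):+.2f} %")
print(f"peak strain rate    : {peak_value(curve.strain_rate):+.2f} 1/s")
print(f"flagged matches     : {int(tracked.low_confidence.sum())}")

# The tracked peak should land within ~2 percentage points of the planted
# value.  For this sin^2 waveform |SR| peaks at 0.25*pi/T (~1.2 1/s here);
# the signed extremum may fall on either the contraction or the recovery
# half-cycle, since both have the same analytic magnitude.
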