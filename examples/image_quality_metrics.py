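"""Blood-myocardium contrast ratio and sigmoid interface sharpness.

Renders the phantom, measures the contrast ratio from label-map ROIs,
and fits the four-parameter sigmoid to a profile crossing the
lung-liver analog interface; the slope parameter is the sharpness.
"""

import numpy as np

from xdsimba import (
    default_phantom_spec,
    extract_profile,
    interface_sharpness,
    render_phantom,
    roi_contrast_ratio,
)
from xdsimba.metrics import ProfileLine

spec = default_phantom_spec(96, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
vol, labels = render_phantom(spec, 0.0)

cr = roi_contrast_ratio(vol, labels, blood_label=1, myo_label=2)
print(f"blood/myocardium contrast ratio: {cr:.3f} "
      f"(planted intensities 1.0 vs 0.3 -> ideal {(1.0 - 0.3) / 0.3:.3f})")

# profile along the SI axis through the lung-liver interface
n = 96
p0 = ((0.5 - 0.16) * n, 0.5 * n - 0.30 * n)
p1 = ((0.5 - 0.16) * n, 0.5 * n + 0.30 * n)
fit = interface_sharpness(extract_profile(np.abs(vol), p0, p1))
print(f"lung-liver sharpness at native resolution: {abs(fit.slope):.2f} per voxel")

# a synthetic profile with known slope shows the fit's recovery accuracy
t = np.linspace(0, 10, 64)
known = 1.0 + 2.0 / (1.0 + np.exp(-2.0 * (t - 5.0)))
fit2 = interface_sharpness(ProfileLine(t, known))
print(f"known slope 2.0 recovered as {fit2.slope:.4f}")
# Contrast is slightly below ideal from partial-volume voxels at ROI
# edges; the recovered slope shows the fit is exact on clean profiles.
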