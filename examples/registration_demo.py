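"""Estimate a non-rigid deformation field and verify it.

Translates a textured phantom by a known amount, registers the pair
with the multiresolution B-spline method, and reports the mean endpoint
error of the recovered field plus the image residual before and after
warping — the same operator (with its exact adjoint) that enters the
motion-compensated reconstruction.
"""

import numpy as np

from xdsimba import default_phantom_spec, estimate_deformation, render_phantom, warp

n = 64
spec = default_phantom_spec(n, ndim=2, cardiac_amplitude=0.0, resp_amplitude=0.0)
img = np.abs(render_phantom(spec, 0.0)[0])
gx, gy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
img *= 1.0 + 0.25 * np.sin(2 * np.pi * gx / 9.0) * np.sin(2 * np.pi * gy / 7.0)

shift = (2, -3)  # voxels
reference = np.roll(img, shift, axis=(0, 1))
field = estimate_deformation(img, reference)

support = reference > 0.1
epe = np.linalg.norm(field.displacement + np.array(shift), axis=-1)
print(f"true displacement: {(-shift[0], -shift[1])} voxels (pull-back convention)")
print(f"mean endpoint error on support: {epe[support].mean():.3f} voxels")
print(f"residual |moving - reference|:  {np.linalg.norm(img - reference):.3f}")
print(f"residual after warping:         {np.linalg.norm(warp(img, field) - reference):.3f}")
# A sub-0.1-voxel endpoint error and a near-zero residual mean the field
# can align adjacent-cluster anatomy before the sparsity penalty acts.
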