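"""Non-rigid deformation: estimation between adjacent-cluster images and
a linear warping operator T_u with an exact adjoint.

Convention is pull-back: ``warp(x, u)(r) = x(r + u(r))`` with u in voxel
units, so the field attached to cluster i deforms its image to match
cluster i-1 (cyclically). The warp is linear interpolation applied to
real and imaginary parts; its adjoint is the literal transpose of the
interpolation-weight matrix (scatter), which the iterative solver needs —
approximating the adjoint by warping with -u would break the
normal-equation symmetry.

Field estimation wraps SimpleITK's multiresolution B-spline free-form
registration (the in-vivo chain used an external registration package
the same way). Full-image metric sampling keeps it deterministic; the
default similarity is normalized cross-correlation (synthetic images
share contrast), with normalized mutual information as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk


@dataclass
class DeformationField:
    """Per-voxel displacement (voxel units) on the image grid.

    displacement[..., d] moves along numpy axis d; identity is all-zero.
    """

    displacement: np.ndarray  # (*grid, ndim)
    pair_id: tuple = (0, 0)
    converged: bool = True
    _interp: tuple = field(default=None, repr=False, compare=False)

    @property
    def grid_shape(self) -> tuple:
        return self.displacement.shape[:-1]

    @property
    def ndim(self) -> int:
        return self.displacement.shape[-1]

    @classmethod
    def identity(cls, grid_shape, pair_id=(0, 0)) -> "DeformationField":
        return cls(np.zeros(tuple(grid_shape) + (len(grid_shape),)), pair_id)

    def _weights(self):
        """Cached (corner indices, weights) of the interpolation matrix."""
        if self._interp is None:
            shape = self.grid_shape
            nd = self.ndim
            grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
            pos = [g + self.displacement[..., d] for d, g in enumerate(grids)]
            # nearest-edge clamp for out-of-grid lookups
            pos = [np.clip(p, 0.0, n - 1.0) for p, n in zip(pos, shape)]
            lo = [np.minimum(np.floor(p), n - 2).astype(np.int64) for p, n in zip(pos, shape)]
            fr = [p - l for p, l in zip(pos, lo)]
            n_vox = int(np.prod(shape))
            idx = np.zeros((n_vox, 2**nd), dtype=np.int64)
            wgt = np.ones((n_vox, 2**nd))
            strides = np.ones(nd, dtype=np.int64)
            for d in range(nd - 2, -1, -1):
                strides[d] = strides[d + 1] * shape[d + 1]
            for corner in range(2**nd):
                flat = np.zeros(shape, dtype=np.int64)
                w = np.ones(shape)
                for d in range(nd):
                    bit = (corner >> d) & 1
                    flat += (lo[d] + bit) * strides[d]
                    w *= fr[d] if bit else (1.0 - fr[d])
                idx[:, corner] = flat.ravel()
                wgt[:, corner] = w.ravel()
            object.__setattr__(self, "_interp", (idx, wgt))
        return self._interp


def warp(x: np.ndarray, u: DeformationField) -> np.ndarray:
    """Apply T_u: linear-interpolation pull-back of ``x`` along ``u``."""
    if x.shape != u.grid_shape:
        raise ValueError("image/field grid mismatch")
    if not u.displacement.any():
        return x.copy()
    idx, wgt = u._weights()
    out = np.sum(x.ravel()[idx] * wgt, axis=1)
    return out.reshape(x.shape).astype(x.dtype, copy=False)


def warp_adjoint(y: np.ndarray, u: DeformationField) -> np.ndarray:
    """Exact transpose of :func:`warp` (interpolation-weight scatter)."""
    if y.shape != u.grid_shape:
        raise ValueError("image/field grid mismatch")
    if not u.displacement.any():
        return y.copy()
    idx, wgt = u._weights()
    out = np.zeros(y.size, dtype=complex if np.iscomplexobj(y) else float)
    np.add.at(out, idx.ravel(), (y.ravel()[:, None] * wgt).ravel())
    return out.reshape(y.shape)


def _to_sitk(img: np.ndarray) -> sitk.Image:
    return sitk.GetImageFromArray(np.ascontiguousarray(img, dtype=np.float64))


def estimate_deformation(
    moving: np.ndarray,
    reference: np.ndarray,
    max_iters: int = 300,
    levels: int = 3,
    metric: str = "ncc",
    control_spacing: float = 8.0,
    pair_id: tuple = (0, 0),
) -> DeformationField:
    """Estimate u such that warp(moving, u) matches reference.

    Multiresolution B-spline free-form registration (control-point
    spacing ``control_spacing`` voxels at the finest level), optimized by
    L-BFGS-B with at most ``max_iters`` iterations per level. Complex
    inputs are registered on their magnitude. Never raises on
    non-convergence: if the registered residual is no better than the
    unregistered one, the identity field is returned with
    ``converged=False``.
    """
    if moving.shape != reference.shape:
        raise ValueError("moving/reference grid mismatch")
    mov = np.abs(moving).astype(np.float64)
    ref = np.abs(reference).astype(np.float64)
    scale = max(ref.max(), 1e-30)
    mov, ref = mov / scale, ref / scale

    # single-threaded metric evaluation keeps the optimization bitwise
    # deterministic (parallel reductions are order-dependent)
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    fixed_img = _to_sitk(ref)
    moving_img = _to_sitk(mov)

    mesh = [max(2, int(round(n / control_spacing))) for n in fixed_img.GetSize()]
    tx0 = sitk.BSplineTransformInitializer(fixed_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    if metric == "ncc":
        reg.SetMetricAsCorrelation()
    elif metric == "nmi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=int(max_iters),
        maximumNumberOfCorrections=5,
    )
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SetInitialTransform(tx0, inPlace=True)
    try:
        tx = reg.Execute(fixed_img, moving_img)
    except RuntimeError:
        return DeformationField.identity(ref.shape, pair_id)

    disp_img = sitk.TransformToDisplacementField(
        tx,
        sitk.sitkVectorFloat64,
        fixed_img.GetSize(),
        fixed_img.GetOrigin(),
        fixed_img.GetSpacing(),
        fixed_img.GetDirection(),
    )
    disp = sitk.GetArrayFromImage(disp_img)  # (..., [x,y,z]) world = index here
    # SimpleITK vector order is (x, y, z) = reversed numpy axis order
    disp = disp[..., ::-1]
    u = DeformationField(np.ascontiguousarray(disp), pair_id)

    # guardrail: registration must not increase the residual
    res_before = np.linalg.norm(mov - ref)
    res_after = np.linalg.norm(np.abs(warp(mov, u)) - ref)
    if not np.isfinite(res_after) or res_after > res_before:
        return DeformationField(
            np.zeros_like(u.displacement), pair_id, converged=False
        )
    return u


def estimate_cyclic_fields(
    volumes: list[np.ndarray],
    max_iters: int = 300,
    metric: str = "ncc",
    smooth_sigma: float = 0.0,
) -> list[DeformationField]:
    """One field per cluster i deforming x^(i) onto x^(i-1), cyclically
    (the pair (first, last) closes the loop since x^(0) = x^(K)).

    Fields are estimated once from the gridded images and kept frozen in
    the iterative reconstruction. ``smooth_sigma`` optionally smooths
    the magnitude images before registration (helps with streaking at
    high undersampling).
    """
    from scipy.ndimage import gaussian_filter

    K = len(volumes)
    mags = [np.abs(v) for v in volumes]
    if smooth_sigma > 0:
        mags = [gaussian_filter(m, smooth_sigma) for m in mags]
    fields = []
    for i in range(K):
        ref = mags[(i - 1) % K]
        fields.append(
            estimate_deformation(
                mags[i], ref, max_iters=max_iters, metric=metric,
                pair_id=(i, (i - 1) % K),
            )
        )
    return fields
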