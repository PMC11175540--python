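"""Gridded (direct) reconstruction and coil handling.

The gridded chain — density compensation, adjoint NUFFT, coil
combination with the conjugate sensitivities — produces the per-cluster
images used both as the fast "most populated cluster" reconstruction and
as the initialization/registration inputs of the iterative solvers.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .nufft import NufftOperator, density_weights
from .phantom import CoilSensitivities, KSpaceData

SUPPORT_EPS = 0.05  # support threshold, fraction of peak RSS


def estimate_sensitivities(
    kdata: KSpaceData,
    grid_size: int,
    readout_subset: np.ndarray | None = None,
    kmax: float = 0.125,
    smooth_sigma: float = 2.0,
) -> CoilSensitivities:
    """Estimate smooth coil maps from the central k-space region.

    Per-coil low-resolution images are gridded from samples with
    |k| < ``kmax``, lightly smoothed, and divided by their
    root-sum-of-squares; low-signal background voxels are filled with the
    nearest on-support value so the maps stay smooth across the support
    edge. RSS of the returned maps is exactly 1 on support.
    """
    traj = kdata.traj
    if readout_subset is None:
        readout_subset = traj.imaging_readouts()
    shape = (grid_size,) * traj.ndim
    coords = traj.coords[readout_subset].reshape(-1, traj.ndim)
    y = kdata.samples[readout_subset].reshape(-1, kdata.n_coils)
    radius = np.linalg.norm(coords, axis=1)
    keep = radius < kmax
    if not np.any(keep) or not np.any(np.abs(y)):
        raise RuntimeError("no usable calibration data")
    coords, y, radius = coords[keep], y[keep], radius[keep]
    # cosine taper avoids ringing from the hard k-space cutoff
    taper = np.cos(0.5 * np.pi * radius / kmax) ** 2
    w = density_weights(coords, ndim=traj.ndim) * taper
    op = NufftOperator(shape, coords)
    imgs = np.stack([op.adjoint(w * y[:, c]) for c in range(kdata.n_coils)])
    imgs = gaussian_filter(imgs.real, smooth_sigma, axes=range(1, imgs.ndim)) + 1j * gaussian_filter(
        imgs.imag, smooth_sigma, axes=range(1, imgs.ndim)
    )
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    support = rss > SUPPORT_EPS * rss.max()
    maps = np.zeros_like(imgs)
    nz = rss > 0
    maps[:, nz] = imgs[:, nz] / rss[nz]
    if support.any() and not support.all():
        # propagate nearest on-support value into the background
        idx = distance_transform_edt(~support, return_distances=False, return_indices=True)
        maps = maps[(slice(None),) + tuple(idx)]
    return CoilSensitivities(maps)


def gridded_recon(
    kdata: KSpaceData,
    readout_subset: np.ndarray,
    sens: CoilSensitivities,
    grid_size: int | None = None,
    dcf_method: str = "pipe",
) -> np.ndarray:
    """Density-compensated adjoint-NUFFT reconstruction of one readout
    subset (the original similarity-binned image when the subset is the
    most populated cluster).

    x = sum_c conj(C_c) * F_adj(w * y_c) / max(RSS(C)^2, eps)

    Density compensation defaults to iteratively refined (Pipe-Menon
    style) weights, which keep the amplitude of a dense acquisition
    correct; ``dcf_method="ramp"`` selects the analytic |k|^(d-1) ramp.
    """
    readout_subset = np.asarray(readout_subset)
    if readout_subset.size == 0:
        raise ValueError("empty readout subset")
    traj = kdata.traj
    if grid_size is None:
        grid_size = sens.maps.shape[1]
    shape = (grid_size,) * traj.ndim
    coords = traj.coords[readout_subset].reshape(-1, traj.ndim)
    y = kdata.samples[readout_subset].reshape(-1, kdata.n_coils)
    w = density_weights(
        coords,
        ndim=traj.ndim,
        method=dcf_method,
        over_shape=tuple(2 * n for n in shape),
    )
    op = NufftOperator(shape, coords)
    acc = np.zeros(shape, dtype=complex)
    for c in range(kdata.n_coils):
        acc += np.conj(sens.maps[c]) * op.adjoint(w * y[:, c])
    rss2 = np.sum(np.abs(sens.maps) ** 2, axis=0)
    denom = np.maximum(rss2, 1e-6)
    return acc / denom


def nrmse(x: np.ndarray, ref: np.ndarray, scale_invariant: bool = True) -> float:
    """Normalized RMS error of |x| against |ref|.

    With ``scale_invariant`` the magnitude of x is first scaled by the
    least-squares factor onto |ref| (reconstructions carry an arbitrary
    global scale).
    """
    a = np.abs(np.asarray(x)).ravel()
    b = np.abs(np.asarray(ref)).ravel()
    if scale_invariant:
        denom = float(a @ a)
        if denom > 0:
            a = a * float(a @ b) / denom
    return float(np.linalg.norm(a - b) / np.linalg.norm(b))
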