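"""Image-quality metrics: blood-myocardium contrast ratio and sigmoid-fit
interface sharpness.

Sharpness is the slope parameter of a four-parameter sigmoid

    s(t) = L + (U - L) / (1 + exp(-a (t - t0)))

least-squares fitted to an intensity profile crossing a tissue
interface; ``a`` (per unit position) is reported. The contrast ratio is
(blood - myocardium) / myocardium of ROI mean magnitudes. Both are
invariant to global intensity scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import OptimizeWarning, curve_fit


@dataclass
class ProfileLine:
    """Samples along a line segment crossing an interface."""

    positions: np.ndarray  # strictly increasing, voxels (or mm)
    intensities: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size < 8:
            raise ValueError("profile needs at least 8 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must strictly increase")
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions/intensities length mismatch")


@dataclass
class SharpnessFit:
    slope: float  # the sharpness value a (NaN if the fit failed)
    center: float
    lower: float
    upper: float
    ok: bool

    def __float__(self):
        return self.slope


def extract_profile(volume: np.ndarray, start, end, supersample: int = 4) -> ProfileLine:
    """Sample |volume| along the segment start->end (voxel coordinates)
    by linear interpolation at ``supersample`` points per voxel."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(end - start))
    n = max(int(np.ceil(length * supersample)) + 1, 8)
    t = np.linspace(0.0, 1.0, n)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    vals = map_coordinates(np.abs(volume), pts.T, order=1, mode="nearest")
    return ProfileLine(t * length, vals)


def _sigmoid(t, lower, upper, a, t0):
    z = np.clip(-a * (t - t0), -700.0, 700.0)  # avoid exp overflow
    return lower + (upper - lower) / (1.0 + np.exp(z))


def interface_sharpness(p: ProfileLine) -> SharpnessFit:
    """Fit the sigmoid and return its slope parameter.

    Initialization: plateau means from the outer quarters, midpoint
    crossing for t0, finite-difference estimate for a. Degenerate (flat)
    or non-convergent profiles return slope NaN with ``ok=False`` —
    never a silent number.
    """
    t, v = p.positions, p.intensities
    n = len(t)
    q = max(n // 4, 2)
    lo0, up0 = float(np.mean(v[:q])), float(np.mean(v[-q:]))
    vrange = up0 - lo0
    if abs(vrange) < 1e-12 * max(abs(up0), abs(lo0), 1e-30) or np.ptp(v) == 0:
        return SharpnessFit(np.nan, np.nan, lo0, up0, False)
    mid = 0.5 * (lo0 + up0)
    cross = np.argmin(np.abs(v - mid))
    t0_0 = float(t[cross])
    # slope of v at the crossing -> a = 4 * slope / (U - L)
    dv = np.gradient(v, t)
    a0 = float(np.clip(4.0 * dv[cross] / vrange, -50.0, 50.0))
    if a0 == 0:
        a0 = np.sign(vrange) * 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _sigmoid,
                t,
                v,
                p0=[lo0, up0, a0, t0_0],
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return SharpnessFit(np.nan, t0_0, lo0, up0, False)
    lower, upper, a, t0 = popt
    if not np.isfinite(a):
        return SharpnessFit(np.nan, t0, lower, upper, False)
    return SharpnessFit(float(a), float(t0), float(lower), float(upper), True)


def contrast_ratio(blood_mean: float, myo_mean: float) -> float:
    """(blood - myocardium) / myocardium of mean signal intensities."""
    if myo_mean <= 0:
        raise ValueError("myocardial mean intensity must be positive")
    return (blood_mean - myo_mean) / myo_mean


def roi_contrast_ratio(volume: np.ndarray, labels: np.ndarray, blood_label: int, myo_label: int) -> float:
    """Contrast ratio from label-map ROIs on a magnitude image."""
    mag = np.abs(volume)
    blood = float(mag[labels == blood_label].mean())
    myo = float(mag[labels == myo_label].mean())
    return contrast_ratio(blood, myo)
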