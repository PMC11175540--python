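"""Radial k-space trajectories for free-running acquisitions.

Generates the 3D spiral-phyllotaxis "kooshball" trajectory (golden-angle
rotation between interleaves, endpoints covering the sphere in a
sunflower-like pattern) and, for desk-scale work, 2D golden-angle spokes.
Superior–inferior (SI) self-gating readouts are interleaved at the
interleave rate; their 1D projections drive the similarity clustering.

Conventions fixed package-wide: k-space coordinates are normalized to
cycles per voxel, each axis in [-0.5, 0.5); the SI axis is the *last*
coordinate axis (z in 3D, y in 2D); voxel indices are 0-based and image
positions are centered at the grid midpoint ``n - N//2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 2D radial golden angle pi/phi ~ 111.246 deg (Winkelmann spoke increment)
GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0
# sunflower golden angle 2*pi/phi^2 ~ 137.508 deg (phyllotaxis azimuth step)
SUNFLOWER_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class RadialTrajectory:
    """A set of straight diameter readouts through the k-space center.

    Attributes
    ----------
    coords : (n_readouts, samples_per_readout, ndim) float64
        Sample positions, cycles/voxel in [-0.5, 0.5).
    interleave_id, readout_in_interleave : (n_readouts,) int
    is_si : (n_readouts,) bool
        Exactly one SI readout per interleave when SI is enabled.
    timestamp : (n_readouts,) float, seconds, strictly increasing.
    """

    coords: np.ndarray
    interleave_id: np.ndarray
    readout_in_interleave: np.ndarray
    is_si: np.ndarray
    timestamp: np.ndarray
    n_interleaves: int
    readouts_per_interleave: int
    samples_per_readout: int
    ndim: int
    tr: float = 0.003
    directions: np.ndarray = field(default=None, repr=False)

    @property
    def n_readouts(self) -> int:
        return self.n_interleaves * self.readouts_per_interleave

    @property
    def has_si(self) -> bool:
        return bool(self.is_si.any())

    def imaging_readouts(self) -> np.ndarray:
        """Indices of non-SI (imaging) readouts."""
        return np.flatnonzero(~self.is_si)

    def validate(self) -> None:
        n = self.n_readouts
        if self.coords.shape != (n, self.samples_per_readout, self.ndim):
            raise ValueError("coords shape inconsistent with counts")
        if not np.all(np.diff(self.timestamp) > 0):
            raise ValueError("timestamps must strictly increase")
        if np.any(self.coords < -0.5) or np.any(self.coords >= 0.5):
            raise ValueError("coordinates outside [-0.5, 0.5)")


def _radial_samples(samples_per_readout: int) -> np.ndarray:
    """Signed radii of a full-diameter readout, in [-0.5, 0.5)."""
    s = np.arange(samples_per_readout)
    return (s - samples_per_readout // 2) / samples_per_readout


def _phyllotaxis_directions(n_points: int) -> np.ndarray:
    """Unit endpoint directions on the upper hemisphere.

    Sunflower pattern: azimuth advances by the golden angle per point,
    polar angle follows the equal-area law cos(theta) = 1 - (n+1/2)/N
    (theta grows like sqrt(n/N) near the pole), which makes the
    symmetrized endpoint set statistically uniform on the sphere.
    """
    n = np.arange(n_points)
    phi = n * SUNFLOWER_ANGLE
    cos_theta = 1.0 - (n + 0.5) / n_points
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    return np.stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta], axis=1
    )


def generate_trajectory(
    n_interleaves: int,
    readouts_per_interleave: int,
    samples_per_readout: int,
    ndim: int = 3,
    include_si: bool = True,
    tr: float = 0.003,
) -> RadialTrajectory:
    """Build a golden-angle radial trajectory with optional SI readouts.

    In 3D, imaging-readout endpoints follow a spiral-phyllotaxis pattern
    distributed over interleaves (interleave m takes every
    n_interleaves-th point starting at m and is rotated by m golden
    angles about z). In 2D, spoke azimuths advance by the golden angle
    per imaging readout. If ``include_si``, the first readout of every
    interleave points along the SI axis (+z in 3D, +y in 2D).
    """
    if n_interleaves < 1 or readouts_per_interleave < 1 or samples_per_readout < 1:
        raise ValueError("counts must be >= 1")
    if samples_per_readout % 2:
        raise ValueError("samples_per_readout must be even")
    if ndim not in (2, 3):
        raise ValueError("ndim must be 2 or 3")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if include_si and readouts_per_interleave < 2:
        raise ValueError("SI readouts need readouts_per_interleave >= 2")

    rpi = readouts_per_interleave
    n_readouts = n_interleaves * rpi
    im_per_int = rpi - 1 if include_si else rpi
    n_imaging = n_interleaves * im_per_int

    directions = np.zeros((n_readouts, ndim))
    is_si = np.zeros(n_readouts, dtype=bool)

    if ndim == 3:
        base = _phyllotaxis_directions(max(n_imaging, 1))
    if include_si:
        si_dir = np.zeros(ndim)
        si_dir[-1] = 1.0

    for m in range(n_interleaves):
        offset = 0
        if include_si:
            ridx = m * rpi
            directions[ridx] = si_dir
            is_si[ridx] = True
            offset = 1
        for j in range(im_per_int):
            ridx = m * rpi + offset + j
            g = j * n_interleaves + m  # global imaging index
            if ndim == 3:
                d = base[g % n_imaging]
                rot = m * SUNFLOWER_ANGLE
                c, s = np.cos(rot), np.sin(rot)
                directions[ridx] = [
                    c * d[0] - s * d[1],
                    s * d[0] + c * d[1],
                    d[2],
                ]
            else:
                az = g * GOLDEN_ANGLE
                directions[ridx] = [np.cos(az), np.sin(az)]

    radii = _radial_samples(samples_per_readout)
    coords = directions[:, None, :] * radii[None, :, None]

    traj = RadialTrajectory(
        coords=coords,
        interleave_id=np.repeat(np.arange(n_interleaves), rpi),
        readout_in_interleave=np.tile(np.arange(rpi), n_interleaves),
        is_si=is_si,
        timestamp=np.arange(n_readouts) * tr,
        n_interleaves=n_interleaves,
        readouts_per_interleave=rpi,
        samples_per_readout=samples_per_readout,
        ndim=ndim,
        tr=tr,
        directions=directions,
    )
    traj.validate()
    return traj


def si_schedule(traj: RadialTrajectory) -> list[tuple[float, int]]:
    """(timestamp, interleave_id) of each SI readout, in acquisition order.

    The mean SI rate is 1 / (readouts_per_interleave * tr); with the
    in-vivo protocol (22 readouts, TR 2.84 ms) this is the ~16 Hz
    self-gating rate.
    """
    if not traj.has_si:
        raise RuntimeError("trajectory has no SI readouts")
    idx = np.flatnonzero(traj.is_si)
    return [(float(traj.timestamp[i]), int(traj.interleave_id[i])) for i in idx]
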