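"""File formats: the HDF5 raw container, NIfTI volumes and deformation
fields, YAML configuration.

Raw-container schema (schema_version 1):

    /kspace    complex64 [n_readouts, samples_per_readout, n_coils]
    /traj      float64   [n_readouts, samples_per_readout, ndim]
    /is_si     uint8     [n_readouts]
    /timestamp float64   [n_readouts]
    /si/projections  complex64 [n_z, n_si, n_coils]     (optional)
    /coils     complex64 [n_coils, *grid]               (optional truth)
    /truth/*   ground-truth phase labels etc.           (optional)
    attrs: tr, n_interleaves, readouts_per_interleave, grid_size,
           voxel_size, schema_version
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .motion import DeformationField
from .phantom import CoilSensitivities, KSpaceData
from .trajectory import RadialTrajectory

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    pass


def write_container(
    path,
    kdata: KSpaceData,
    coils: CoilSensitivities | None = None,
    grid_size: int | None = None,
    voxel_size: float = 1.0,
) -> None:
    traj = kdata.traj
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kdata.samples.astype(np.complex64))
        f.create_dataset("traj", data=traj.coords.astype(np.float64))
        f.create_dataset("is_si", data=traj.is_si.astype(np.uint8))
        f.create_dataset("timestamp", data=traj.timestamp.astype(np.float64))
        if kdata.si_projections is not None:
            f.create_dataset(
                "si/projections", data=kdata.si_projections.astype(np.complex64)
            )
        if coils is not None:
            f.create_dataset("coils", data=coils.maps.astype(np.complex64))
        if kdata.truth:
            g = f.create_group("truth")
            for k, v in kdata.truth.items():
                g.create_dataset(k, data=np.asarray(v))
        f.attrs["tr"] = traj.tr
        f.attrs["n_interleaves"] = traj.n_interleaves
        f.attrs["readouts_per_interleave"] = traj.readouts_per_interleave
        f.attrs["grid_size"] = grid_size if grid_size is not None else 0
        f.attrs["voxel_size"] = voxel_size
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_container(path):
    """Returns (KSpaceData, RadialTrajectory, CoilSensitivities | None).

    Ground truth, when present, is attached as ``kdata.truth``.
    Round-trips :func:`write_container` losslessly at the stored
    precision.
    """
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SchemaError("missing schema_version attribute")
        if int(version) != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version={int(version)}")
        for name in ("kspace", "traj", "is_si", "timestamp"):
            if name not in f:
                raise SchemaError(f"missing /{name}")
        samples = f["kspace"][()].astype(np.complex64)
        coords = f["traj"][()]
        is_si = f["is_si"][()].astype(bool)
        timestamp = f["timestamp"][()]
        n_int = int(f.attrs["n_interleaves"])
        rpi = int(f.attrs["readouts_per_interleave"])
        traj = RadialTrajectory(
            coords=coords,
            interleave_id=np.repeat(np.arange(n_int), rpi),
            readout_in_interleave=np.tile(np.arange(rpi), n_int),
            is_si=is_si,
            timestamp=timestamp,
            n_interleaves=n_int,
            readouts_per_interleave=rpi,
            samples_per_readout=coords.shape[1],
            ndim=coords.shape[2],
            tr=float(f.attrs["tr"]),
        )
        si_proj = f["si/projections"][()].astype(np.complex64) if "si/projections" in f else None
        truth = {}
        if "truth" in f:
            truth = {k: f["truth"][k][()] for k in f["truth"]}
        coils = None
        if "coils" in f:
            coils = CoilSensitivities(f["coils"][()].astype(np.complex64))
    kdata = KSpaceData(samples=samples, traj=traj, si_projections=si_proj, truth=truth)
    return kdata, traj, coils


def save_volume(path, volume: np.ndarray, voxel_size: float = 1.0, complex_pair: bool = False) -> None:
    """Write a volume as NIfTI (magnitude float32; optionally a second
    file with the real/imag pair stacked on a trailing axis)."""
    vol = np.asarray(volume)
    affine = np.diag([voxel_size] * vol.ndim + [1.0])[: vol.ndim + 1, : vol.ndim + 1]
    aff4 = np.eye(4)
    aff4[: vol.ndim, : vol.ndim] = affine[: vol.ndim, : vol.ndim]
    nib.save(nib.Nifti1Image(np.abs(vol).astype(np.float32), aff4), str(path))
    if complex_pair:
        pair = np.stack([vol.real, vol.imag], axis=-1).astype(np.float32)
        p = Path(path)
        nib.save(nib.Nifti1Image(pair, aff4), str(p.with_name(p.stem.split(".")[0] + "_complex.nii.gz")))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_deformation(path, field: DeformationField, voxel_size: float = 1.0) -> None:
    """Deformation field as a NIfTI vector image (trailing component
    axis, voxel units) plus a JSON sidecar with the pair metadata."""
    disp = field.displacement.astype(np.float32)
    aff4 = np.eye(4)
    nd = disp.ndim - 1
    aff4[:nd, :nd] *= voxel_size
    nib.save(nib.Nifti1Image(disp, aff4), str(path))
    p = Path(path)
    sidecar = p.with_suffix("").with_suffix(".json") if p.suffix == ".gz" else p.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"pair_id": list(field.pair_id), "converged": bool(field.converged)})
    )


def load_deformation(path) -> DeformationField:
    disp = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    p = Path(path)
    sidecar = p.with_suffix("").with_suffix(".json") if p.suffix == ".gz" else p.with_suffix(".json")
    pair, conv = (0, 0), True
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pair = tuple(meta.get("pair_id", (0, 0)))
        conv = bool(meta.get("converged", True))
    return DeformationField(disp, pair, conv)


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
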