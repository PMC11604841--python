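"""HDF5 / NIfTI persistence.

Axis convention: array axis 0 right->left, axis 1 anterior->posterior,
axis 2 inferior->superior; the NIfTI affine maps this to RAS+ with the
stored voxel size.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np

from .phantom import RadialAcquisition
from .trajectory import Trajectory


def nifti_affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([-voxel_size_mm, -voxel_size_mm, voxel_size_mm, 1.0])


def save_nifti(path, data, voxel_size_mm: float = 1.0, extra_header: dict = None):
    img = nib.Nifti1Image(np.asarray(data).astype(np.float32), nifti_affine(voxel_size_mm))
    if extra_header:
        img.header["descrip"] = json.dumps(extra_header)[:79].encode()
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img


def save_acquisition(path, acq: RadialAcquisition):
    with h5py.File(str(path), "w") as f:
        f.create_dataset("kdata", data=acq.kdata.astype(np.complex64))
        f.create_dataset("traj/directions", data=acq.trajectory.directions)
        f.create_dataset("traj/radii", data=acq.trajectory.radii)
        f.create_dataset("traj/dcf", data=acq.trajectory.dcf)
        f.create_dataset("time", data=acq.timestamp_s)
        if acq.coil_maps is not None:
            f.create_dataset("coilmaps", data=acq.coil_maps.astype(np.complex64))
        meta = f.create_group("meta")
        meta.attrs["grid_shape"] = acq.grid_shape
        meta.attrs["voxel_size_mm"] = acq.voxel_size_mm
        meta.attrs["seed"] = acq.seed
        meta.attrs["ramp_fraction"] = acq.trajectory.ramp_fraction


def load_acquisition(path) -> RadialAcquisition:
    with h5py.File(str(path), "r") as f:
        traj = Trajectory(
            directions=f["traj/directions"][()],
            radii=f["traj/radii"][()],
            ramp_fraction=float(f["meta"].attrs["ramp_fraction"]),
            dcf=f["traj/dcf"][()],
        )
        return RadialAcquisition(
            kdata=f["kdata"][()].astype(np.complex128),
            trajectory=traj,
            timestamp_s=f["time"][()],
            coil_maps=f["coilmaps"][()].astype(np.complex128) if "coilmaps" in f else None,
            grid_shape=tuple(int(v) for v in f["meta"].attrs["grid_shape"]),
            voxel_size_mm=float(f["meta"].attrs["voxel_size_mm"]),
            seed=int(f["meta"].attrs["seed"]),
        )


def save_binning(path, binning):
    payload = {
        "n_states": binning.n_states,
        "shared_fraction": binning.shared_fraction,
        "state_amplitude": list(map(float, binning.state_amplitude)),
        "membership": [[[int(s), float(w)] for s, w in m] for m in binning.membership],
    }
    with open(str(path), "w") as f:
        json.dump(payload, f)


def load_binning(path):
    from .gating import PhaseBinning

    with open(str(path)) as f:
        payload = json.load(f)
    return PhaseBinning(
        n_states=payload["n_states"],
        membership=[[(int(s), float(w)) for s, w in m] for m in payload["membership"]],
        shared_fraction=payload["shared_fraction"],
        state_amplitude=np.asarray(payload["state_amplitude"]),
    )
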