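"""Raw-data container and on-disk formats.

Multi-coil Cartesian k-space is held with one row per phase-encode readout
(all ``k_x`` samples of that readout), bound to a :class:`~respmoco.trajectory.Trajectory`
and to per-heartbeat respiratory translations measured from 2D image
navigators.  The container round-trips through an HDF5 file with the layout

    /kspace              complex64  [n_coils, n_readouts, n_x]
    /inav                float32    [n_beats, h, w]      (optional)
    /resp                float32    [n_beats, 2]         (optional, mm)
    /coils               complex64  [n_coils, nx, ny, nz] (optional)
    /trajectory/readouts int32      [N, 2]
    /trajectory/heartbeat int32     [N]
    /trajectory  attrs: n_ky, n_kz, nominal_accel, r_center
    root attrs: n_x, voxel_mm

Volumes are written as NIfTI (nibabel) for inspection; displacement fields
as 4D NIfTI with the vector dimension last, in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

from .trajectory import GridSpec, Trajectory

__all__ = ["KSpaceData", "save_raw", "load_raw", "save_volume", "load_volume", "save_field"]


@dataclass
class KSpaceData:
    """Multi-coil k-space bound to a trajectory.

    ``data[c, r, :]`` is the fully sampled ``k_x`` readout of coil ``c`` at
    the ``r``-th phase-encode location ``traj.readouts[r]``.  ``resp_t_mm``
    holds the per-heartbeat 2D (foot-head, left-right) translation in mm in
    the mean-position-minus-current-position convention used by the k-space
    phase-shift correction.
    """

    data: np.ndarray
    traj: Trajectory
    voxel_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    resp_t_mm: np.ndarray | None = None
    inavs: np.ndarray | None = None
    coils: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("kspace data must be (n_coils, n_readouts, n_x)")
        if self.data.shape[1] != self.traj.n_readouts:
            raise ValueError("kspace rows do not match trajectory readouts")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_x(self) -> int:
        return self.data.shape[2]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return (self.n_x, self.traj.grid.n_ky, self.traj.grid.n_kz)

    def kx_cycles_per_mm(self) -> np.ndarray:
        """Centered k_x coordinates in cycles/mm."""
        n = self.n_x
        return (np.arange(n) - n // 2) / (n * self.voxel_mm[0])

    def ky_cycles_per_mm(self) -> np.ndarray:
        """Per-readout k_y coordinate in cycles/mm."""
        g = self.traj.grid
        return (self.traj.readouts[:, 0] - g.n_ky // 2) / (g.n_ky * self.voxel_mm[1])


def save_raw(path, kdata: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kdata.data.astype(np.complex64))
        grp = f.create_group("trajectory")
        grp.create_dataset("readouts", data=kdata.traj.readouts.astype(np.int32))
        grp.create_dataset("heartbeat", data=kdata.traj.heartbeat.astype(np.int32))
        grp.attrs["n_ky"] = kdata.traj.grid.n_ky
        grp.attrs["n_kz"] = kdata.traj.grid.n_kz
        grp.attrs["nominal_accel"] = kdata.traj.nominal_accel
        grp.attrs["r_center"] = kdata.traj.r_center
        f.attrs["n_x"] = kdata.n_x
        f.attrs["voxel_mm"] = kdata.voxel_mm
        if kdata.resp_t_mm is not None:
            f.create_dataset("resp", data=np.asarray(kdata.resp_t_mm, dtype=np.float32))
        if kdata.inavs is not None:
            f.create_dataset("inav", data=np.asarray(kdata.inavs, dtype=np.float32))
        if kdata.coils is not None:
            f.create_dataset("coils", data=np.asarray(kdata.coils, dtype=np.complex64))


def load_raw(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        grp = f["trajectory"]
        grid = GridSpec(int(grp.attrs["n_ky"]), int(grp.attrs["n_kz"]))
        traj = Trajectory(
            grid,
            grp["readouts"][...],
            grp["heartbeat"][...],
            float(grp.attrs.get("nominal_accel", 1.0)),
            float(grp.attrs.get("r_center", 0.0)),
        )
        return KSpaceData(
            data=f["kspace"][...],
            traj=traj,
            voxel_mm=f.attrs["voxel_mm"],
            resp_t_mm=f["resp"][...] if "resp" in f else None,
            inavs=f["inav"][...] if "inav" in f else None,
            coils=f["coils"][...] if "coils" in f else None,
        )


def save_volume(path, volume: np.ndarray, voxel_mm) -> None:
    """Write a (possibly complex) volume as NIfTI; complex input saves |.|."""
    vol = np.abs(volume) if np.iscomplexobj(volume) else np.asarray(volume)
    affine = np.diag([*np.asarray(voxel_mm, dtype=float), 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def save_field(path, disp: np.ndarray, voxel_mm) -> None:
    """Displacement field (3, nx, ny, nz), voxel units, vector dim last.

    Sign convention: a warped image samples the source at ``x + disp(x)``.
    """
    arr = np.moveaxis(np.asarray(disp, dtype=np.float32), 0, -1)
    affine = np.diag([*np.asarray(voxel_mm, dtype=float), 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header["descrip"] = b"displacement, voxel units, out(x)=in(x+d(x))"
    nib.save(img, str(path))
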