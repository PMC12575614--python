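"""HDF5 container and NIfTI export.

Group layout
------------
/trajectory : coords (N_k x d, float64), times (s), interleave (int32);
              attrs dim, mtx (when known)
/grid       : shape, mask (uint8, full grid, row-major), overdisc
/phantom    : values
/factors    : coil_maps, b0, te, shifts (whichever exist)
/data       : complex k-space samples; attrs row_order
/encode     : matrix; attrs row_order, col_order, precision
/recon      : matrix; attrs method, lambda_rel, energy_keep, kappa;
              /spectrum dataset when available
/metrics    : srf_map, noise_map
"""

from __future__ import annotations

from typing import Optional

import h5py
import nibabel as nib
import numpy as np

from .encoding import EncodeMatrix
from .inversion import ReconOperator, RegularizationSpec
from .trajectories import ImageGrid, KSpaceTrajectory

ROW_ORDER = "coil-outermost, then echo, then k-sample"
COL_ORDER = "species-outermost, then voxel row-major over the mask"


def save_trajectory(h5: h5py.Group, traj: KSpaceTrajectory,
                    mtx: Optional[int] = None) -> None:
    g = h5.require_group("trajectory")
    for name in ("coords", "times", "interleave"):
        if name in g:
            del g[name]
    g.create_dataset("coords", data=traj.coords.astype(np.float64))
    g.create_dataset("times", data=traj.times)
    g.create_dataset("interleave", data=traj.interleave.astype(np.int32))
    g.attrs["dim"] = traj.dim
    if mtx is not None:
        g.attrs["mtx"] = int(mtx)


def load_trajectory(h5: h5py.Group) -> KSpaceTrajectory:
    g = h5["trajectory"]
    return KSpaceTrajectory(coords=g["coords"][()], times=g["times"][()],
                            interleave=g["interleave"][()], dim=int(g.attrs["dim"]))


def save_grid(h5: h5py.Group, grid: ImageGrid) -> None:
    g = h5.require_group("grid")
    for name in ("shape", "mask", "overdisc"):
        if name in g:
            del g[name]
    g.create_dataset("shape", data=np.asarray(grid.shape, dtype=np.int64))
    g.create_dataset("mask", data=grid.mask.astype(np.uint8))
    g.create_dataset("overdisc", data=int(grid.overdisc))


def load_grid(h5: h5py.Group) -> ImageGrid:
    g = h5["grid"]
    return ImageGrid(shape=tuple(g["shape"][()]), mask=g["mask"][()].astype(bool),
                     overdisc=int(g["overdisc"][()]))


def save_data(h5: h5py.Group, data: np.ndarray, name: str = "data") -> None:
    if name in h5:
        del h5[name]
    ds = h5.create_dataset(name, data=np.asarray(data))
    ds.attrs["row_order"] = ROW_ORDER


def save_encode(h5: h5py.Group, enc: EncodeMatrix) -> None:
    g = h5.require_group("encode")
    if "matrix" in g:
        del g["matrix"]
    g.create_dataset("matrix", data=enc.matrix)
    g.attrs.update({"row_order": ROW_ORDER, "col_order": COL_ORDER,
                    "precision": enc.precision, "n_k": enc.n_k,
                    "n_voxels": enc.n_voxels, "n_coils": enc.n_coils,
                    "n_echoes": enc.n_echoes, "n_species": enc.n_species})
    if enc.grid is not None:
        save_grid(h5, enc.grid)


def load_encode(h5: h5py.Group) -> EncodeMatrix:
    g = h5["encode"]
    grid = load_grid(h5) if "grid" in h5 else None
    return EncodeMatrix(matrix=g["matrix"][()], n_k=int(g.attrs["n_k"]),
                        n_voxels=int(g.attrs["n_voxels"]),
                        n_coils=int(g.attrs["n_coils"]),
                        n_echoes=int(g.attrs["n_echoes"]),
                        n_species=int(g.attrs["n_species"]),
                        precision=str(g.attrs["precision"]), grid=grid)


def save_recon(h5: h5py.Group, op: ReconOperator) -> None:
    g = h5.require_group("recon")
    if "matrix" in g:
        del g["matrix"]
    g.create_dataset("matrix", data=op.matrix)
    g.attrs["method"] = op.method
    g.attrs["lambda_rel"] = op.reg.lambda_rel
    if op.reg.energy_keep is not None:
        g.attrs["energy_keep"] = op.reg.energy_keep
    if op.kappa is not None:
        g.attrs["kappa"] = op.kappa
    if op.spectrum is not None:
        if "spectrum" in h5:
            del h5["spectrum"]
        h5.create_dataset("spectrum", data=op.spectrum)


def load_recon(h5: h5py.Group) -> ReconOperator:
    g = h5["recon"]
    reg = RegularizationSpec(
        method="tikhonov" if g.attrs["lambda_rel"] > 0 else "none",
        lambda_rel=float(g.attrs["lambda_rel"]),
        energy_keep=float(g.attrs["energy_keep"]) if "energy_keep" in g.attrs else None)
    spectrum = h5["spectrum"][()] if "spectrum" in h5 else None
    grid = load_grid(h5) if "grid" in h5 else None
    return ReconOperator(matrix=g["matrix"][()], method=str(g.attrs["method"]),
                         reg=reg, spectrum=spectrum,
                         kappa=float(g.attrs["kappa"]) if "kappa" in g.attrs else None,
                         grid=grid)


def save_factors(h5: h5py.Group, coil_maps=None, b0_map=None,
                 echo_times=None, species_shifts=None) -> None:
    g = h5.require_group("factors")
    for name, val in (("coil_maps", coil_maps), ("b0", b0_map),
                      ("te", echo_times), ("shifts", species_shifts)):
        if name in g:
            del g[name]
        if val is not None:
            g.create_dataset(name, data=np.asarray(val))


def grid_affine(grid: ImageGrid, fov_mm: float = 240.0) -> np.ndarray:
    """NIfTI affine from the grid spacing (isotropic FOV in mm)."""
    affine = np.eye(4)
    for ax, n in enumerate(grid.shape[:3]):
        affine[ax, ax] = fov_mm / n
        affine[ax, 3] = -fov_mm / 2.0
    return affine


def save_nifti(path: str, image: np.ndarray, grid: Optional[ImageGrid] = None,
               fov_mm: float = 240.0) -> None:
    """Export a (possibly complex) image volume as NIfTI (magnitude)."""
    image = np.asarray(image)
    if np.iscomplexobj(image):
        image = np.abs(image)
    affine = grid_affine(grid, fov_mm) if grid is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), affine), path)
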