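"""Dense encoding-matrix assembly and Gram-matrix construction.

The encoding matrix maps the flattened image (unknowns) to the measured
k-space samples:  data = Encode @ image.  In the Fourier-only case each entry
is ``exp(+j 2 pi k . r)``; generalized encoding multiplies in receive-coil
sensitivities, chemical-shift/echo-time phases, off-resonance phase accrual,
and spatial coordinate modifications (off-center shift, gradient-nonlinearity
warp, rigid motion).

Index conventions (bit-exact, also recorded in HDF5 attrs):
  rows    : receive coil outermost, then echo, then k-sample
            row = i_rx * (n_TE * N_k) + i_te * N_k + i_k
  columns : chemical species outermost, then voxel in row-major mask order
            col = i_cs * N_r + i_r
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ResourceLimitError
from .phantoms import EncodingFactors
from .trajectories import ImageGrid, KSpaceTrajectory

#: Hard cap on the predicted size of a dense encode matrix (bytes).
DEFAULT_MEMORY_CAP = 16 * 1024 ** 3

_DTYPES = {"single": np.complex64, "double": np.complex128}


@dataclass
class EncodeMatrix:
    """Dense complex N_meas x N_unknown encoding matrix with index semantics."""

    matrix: np.ndarray
    n_k: int
    n_voxels: int
    n_coils: int = 1
    n_echoes: int = 1
    n_species: int = 1
    precision: str = "double"
    grid: Optional[ImageGrid] = None
    traj: Optional[KSpaceTrajectory] = None

    def __post_init__(self) -> None:
        expected = (self.n_coils * self.n_echoes * self.n_k,
                    self.n_species * self.n_voxels)
        if self.matrix.shape != expected:
            raise ValueError(f"matrix shape {self.matrix.shape} != {expected} "
                             "implied by the index semantics")

    @property
    def n_meas(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_unknown(self) -> int:
        return self.matrix.shape[1]

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def subset_rows(self, k_selector) -> "EncodeMatrix":
        """Restrict to selected k-samples (replicated across coils and echoes)."""
        k_selector = np.asarray(k_selector)
        if k_selector.dtype == bool:
            k_idx = np.flatnonzero(k_selector)
        else:
            k_idx = k_selector.ravel()
        if k_idx.size == 0:
            raise ValueError("row selection is empty")
        rows = []
        for i_rx in range(self.n_coils):
            for i_te in range(self.n_echoes):
                base = (i_rx * self.n_echoes + i_te) * self.n_k
                rows.append(base + k_idx)
        rows = np.concatenate(rows)
        traj = self.traj.subset_samples(k_idx) if self.traj is not None else None
        return replace(self, matrix=self.matrix[rows], n_k=k_idx.size, traj=traj)


@dataclass
class GramMatrix:
    """Hermitian (symmetrized) Gram matrix E^H E + lambda^2 I."""

    matrix: np.ndarray
    lambda2: float = 0.0

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Gram matrix must be square")
        if self.lambda2 < 0:
            raise ValueError("lambda2 must be >= 0")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _check_memory(n_rows: int, n_cols: int, dtype, cap: int) -> None:
    predicted = n_rows * n_cols * np.dtype(dtype).itemsize
    if predicted > cap:
        raise ResourceLimitError(
            f"encode matrix would need {predicted / 1024**3:.1f} GiB "
            f"(cap {cap / 1024**3:.1f} GiB); reduce the problem with a grid mask "
            "(circular_mask), coil-wise Gram accumulation (coilwise_gram) or the "
            "block-wise Cholesky route (pinv_cholesky_block)")


def _fourier_phase(k_coords: np.ndarray, r_coords: np.ndarray, dtype) -> np.ndarray:
    """exp(+j 2 pi k . r), shape (N_k, N_r)."""
    return np.exp(2j * np.pi * (k_coords @ r_coords.T)).astype(dtype)


def fourier_encode(traj: KSpaceTrajectory, grid: ImageGrid,
                   precision: str = "single",
                   memory_cap: int = DEFAULT_MEMORY_CAP) -> EncodeMatrix:
    """Plain gradient (Fourier) encoding matrix: entry = exp(j 2 pi k_ik . r_ir)."""
    if precision not in _DTYPES:
        raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")
    if traj.dim != grid.dim:
        raise ValueError(f"trajectory dim {traj.dim} != grid dim {grid.dim}")
    dtype = _DTYPES[precision]
    r = grid.coords
    _check_memory(traj.n_samples, r.shape[0], dtype, memory_cap)
    matrix = _fourier_phase(traj.coords, r, dtype)
    return EncodeMatrix(matrix=matrix, n_k=traj.n_samples, n_voxels=r.shape[0],
                        precision=precision, grid=grid, traj=traj)


def _coils_at(coil_maps: np.ndarray, grid: ImageGrid, coords: np.ndarray) -> np.ndarray:
    """Evaluate grid-sampled coil maps at (possibly shifted) coordinates.

    Exact grid coordinates are read off directly; anything else goes through
    linear interpolation with nearest-value extrapolation beyond the FOV.
    """
    coil_maps = np.atleast_2d(coil_maps)
    axes = [(np.arange(n) - n / 2.0) / n for n in grid.shape]
    out = np.empty((coil_maps.shape[0], coords.shape[0]), dtype=complex)
    for m, cmap in enumerate(coil_maps):
        field = cmap.reshape(grid.shape)
        interp = RegularGridInterpolator(axes, field, method="linear",
                                         bounds_error=False, fill_value=None)
        out[m] = interp(coords)
    return out


def build_encode(traj: KSpaceTrajectory, grid: ImageGrid,
                 factors: Optional[EncodingFactors] = None,
                 precision: str = "single",
                 memory_cap: int = DEFAULT_MEMORY_CAP) -> EncodeMatrix:
    """Generalized encoding matrix.

    Entry ((i_k, i_rx, i_te), (i_r, i_cs)) =
        exp(j 2 pi k_ik . warp(r_ir + dr)) * Coil_irx(r_ir + dr)
        * exp(j dCS_ics * TE_ite) * exp(j dB0_ir * t_ik)

    Omitted factors default to the identity, reducing exactly to
    :func:`fourier_encode`.
    """
    if factors is None:
        factors = EncodingFactors()
    if precision not in _DTYPES:
        raise ValueError(f"precision must be 'single' or 'double', got {precision!r}")
    if traj.dim != grid.dim:
        raise ValueError(f"trajectory dim {traj.dim} != grid dim {grid.dim}")
    if factors.b0_map is not None and np.all(traj.times == 0) \
            and np.any(np.asarray(factors.b0_map) != 0):
        raise ValueError("b0_map given but the trajectory carries no readout times")
    if factors.echo_times is not None and factors.species_shifts is None:
        raise ValueError("echo_times given without species_shifts")

    dtype = _DTYPES[precision]
    n_rx, n_te, n_cs = factors.n_coils, factors.n_echoes, factors.n_species
    n_r = grid.n_voxels
    _check_memory(n_rx * n_te * traj.n_samples, n_cs * n_r, dtype, memory_cap)

    r = grid.coords
    if factors.off_center is not None:
        r_shift = r + np.asarray(factors.off_center, dtype=float)
    else:
        r_shift = r
    r_enc = factors.warp(r_shift) if factors.warp is not None else r_shift

    if factors.motion is None:
        base = _fourier_phase(traj.coords, r_enc, dtype)
    else:
        # rigid motion makes the spatial coordinates row (time) dependent
        base = np.empty((traj.n_samples, n_r), dtype=dtype)
        for i_k in range(traj.n_samples):
            rot, dr = factors.motion(traj.times[i_k])
            r_k = r_shift @ np.asarray(rot).T + np.asarray(dr)
            r_k = factors.warp(r_k) if factors.warp is not None else r_k
            base[i_k] = np.exp(2j * np.pi * (traj.coords[i_k] @ r_k.T))

    if factors.b0_map is not None:
        b0 = grid.extract(np.asarray(factors.b0_map, dtype=float))
        base = base * np.exp(1j * np.outer(traj.times, b0)).astype(dtype)

    if factors.coil_maps is not None:
        if factors.off_center is not None or factors.motion is not None:
            coils = _coils_at(factors.coil_maps, grid, r_shift)
        else:
            coils = grid.extract(np.atleast_2d(factors.coil_maps))
    else:
        coils = np.ones((1, n_r))

    shifts = np.atleast_1d(factors.species_shifts) if n_cs > 1 or \
        factors.species_shifts is not None else np.zeros(1)
    tes = np.atleast_1d(factors.echo_times) if factors.echo_times is not None \
        else np.zeros(1)

    blocks = []
    for i_rx in range(n_rx):
        coil_row = base * coils[i_rx][None, :].astype(dtype)
        for i_te in range(n_te):
            species_cols = [coil_row * dtype(np.exp(1j * shifts[i_cs] * tes[i_te]))
                            for i_cs in range(n_cs)]
            blocks.append(np.concatenate(species_cols, axis=1)
                          if n_cs > 1 else species_cols[0])
    matrix = np.concatenate(blocks, axis=0) if len(blocks) > 1 else blocks[0]
    return EncodeMatrix(matrix=matrix, n_k=traj.n_samples, n_voxels=n_r,
                        n_coils=n_rx, n_echoes=n_te, n_species=n_cs,
                        precision=precision, grid=grid, traj=traj)


def _symmetrize(g: np.ndarray) -> np.ndarray:
    return 0.5 * (g + g.conj().T)


def largest_eigenvalue(gram: np.ndarray, n_iter: int = 20, tol: float = 1e-6,
                       seed: int = 0) -> float:
    """Largest eigenvalue of a Hermitian PSD matrix by the power method.

    For a raw Gram matrix this equals sigma_max(Encode)^2.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(gram.shape[0]) + 1j * rng.standard_normal(gram.shape[0])
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(n_iter):
        w = gram @ v
        lam_new = float(np.real(np.vdot(v, w)))
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v = w / nw
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1.0):
            lam = lam_new
            break
        lam = lam_new
    return max(lam, 0.0)


def sigma_max(encode) -> float:
    """Estimated largest singular value of the encoding matrix.

    Uses the same seeded power method as :func:`gram`, so every inversion
    route derives an identical Tikhonov lambda from ``lambda_rel``.
    """
    matrix = getattr(encode, "matrix", encode)
    g = _symmetrize(matrix.conj().T.astype(np.complex128)
                    @ matrix.astype(np.complex128))
    return float(np.sqrt(largest_eigenvalue(g)))


def gram(encode, lambda_rel: float = 0.0) -> GramMatrix:
    """Gram matrix E^H E + lambda^2 I with lambda = lambda_rel * sigma_max(E).

    The result is explicitly symmetrized, guarding the Cholesky route against
    rounding asymmetry.
    """
    if lambda_rel < 0:
        raise ValueError("lambda_rel must be >= 0")
    matrix = getattr(encode, "matrix", encode)
    g = _symmetrize(matrix.conj().T.astype(np.complex128) @ matrix.astype(np.complex128))
    lam2 = 0.0
    if lambda_rel > 0:
        lam2 = lambda_rel ** 2 * largest_eigenvalue(g)
        g = g + lam2 * np.eye(g.shape[0])
    return GramMatrix(matrix=g, lambda2=lam2)


def coilwise_gram(traj: KSpaceTrajectory, grid: ImageGrid, coil_maps: np.ndarray,
                  lambda_rel: float = 0.0, precision: str = "double") -> GramMatrix:
    """Gram matrix accumulated coil by coil, never stacking the full Encode.

    Sum over coils of E_c^H E_c (+ lambda^2 I), where
    E_c = Coil_c(r) * exp(j 2 pi k . r).
    """
    coil_maps = np.atleast_2d(coil_maps)
    if coil_maps.shape[0] < 1:
        raise ValueError("at least one coil map is required")
    if lambda_rel < 0:
        raise ValueError("lambda_rel must be >= 0")
    dtype = _DTYPES[precision]
    base = _fourier_phase(traj.coords, grid.coords, dtype)
    g = np.zeros((grid.n_voxels, grid.n_voxels), dtype=np.complex128)
    for cmap in coil_maps:
        e_c = base * grid.extract(cmap)[None, :].astype(dtype)
        g += e_c.conj().T.astype(np.complex128) @ e_c.astype(np.complex128)
    g = _symmetrize(g)
    lam2 = 0.0
    if lambda_rel > 0:
        lam2 = lambda_rel ** 2 * largest_eigenvalue(g)
        g = g + lam2 * np.eye(g.shape[0])
    return GramMatrix(matrix=g, lambda2=lam2)


def coilwise_adjoint(traj: KSpaceTrajectory, grid: ImageGrid, coil_maps: np.ndarray,
                     data: np.ndarray, precision: str = "double") -> np.ndarray:
    """Adjoint applied coil by coil: sum over coils of E_c^H data_c.

    ``data`` is ordered coil-outermost (length n_coils * N_k).
    """
    coil_maps = np.atleast_2d(coil_maps)
    n_rx, n_k = coil_maps.shape[0], traj.n_samples
    data = np.asarray(data).reshape(-1)
    if data.shape[0] != n_rx * n_k:
        raise ValueError(f"data length {data.shape[0]} != n_coils*N_k = {n_rx * n_k}")
    dtype = _DTYPES[precision]
    base = _fourier_phase(traj.coords, grid.coords, dtype)
    out = np.zeros(grid.n_voxels, dtype=np.complex128)
    for c, cmap in enumerate(coil_maps):
        e_c = base * grid.extract(cmap)[None, :].astype(dtype)
        out += e_c.conj().T @ data[c * n_k:(c + 1) * n_k]
    return out


def subset_rows(encode_or_traj, selector):
    """Row subsetting for an EncodeMatrix (k-sample indices/mask) or a
    KSpaceTrajectory (interleave labels)."""
    if isinstance(encode_or_traj, EncodeMatrix):
        return encode_or_traj.subset_rows(selector)
    if isinstance(encode_or_traj, KSpaceTrajectory):
        return encode_or_traj.subset(selector)
    raise TypeError("expected an EncodeMatrix or KSpaceTrajectory")
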