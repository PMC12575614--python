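"""Reconstruction quality metrics derived from the explicit Recon operator.

Because Pinv-Recon materializes Recon = Encode^+, two diagnostics come almost
for free:

* the spatial response function  SRF = Recon @ Encode, whose diagonal says
  what proportion of each voxel's signal ends up in the reconstructed voxel
  (identity is ideal), and
* the noise matrix  X = Recon @ Psi @ Recon^H, the propagated covariance of
  the measurement noise (Psi) in image space.

The module also provides the error measures used by the regularization study
(MSE against the phantom, MSE of reconstructing pure noise, the zero-image
and resolution-limited reference floors) and the sweep driver itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .encoding import fourier_encode
from .errors import DegenerateInputError
from .inversion import RegularizationSpec, truncation_rank
from .phantoms import Phantom, add_noise
from .trajectories import ImageGrid, KSpaceTrajectory


@dataclass
class SRFResult:
    srf_matrix: Optional[np.ndarray]   # N_unknown x N_unknown, if requested
    srf_map: np.ndarray                # real part of the diagonal
    grid: Optional[ImageGrid] = None

    def map_image(self) -> np.ndarray:
        """SRF map embedded into the image grid (zeros outside the mask)."""
        if self.grid is None:
            raise ValueError("no grid attached to this SRF result")
        per_species = self.srf_map.reshape(-1, self.grid.n_voxels)
        if per_species.shape[0] == 1:
            return self.grid.embed(per_species[0])
        return np.stack([self.grid.embed(v) for v in per_species])


@dataclass
class NoiseResult:
    noise_matrix: Optional[np.ndarray]
    noise_map: np.ndarray              # sqrt of the real diagonal (std units)
    grid: Optional[ImageGrid] = None


def srf(recon, encode, full: bool = False) -> SRFResult:
    """Spatial response function SRF = Recon @ Encode.

    Always returns the map (real part of the diagonal); ``full=True`` also
    returns the complete matrix.
    """
    r = getattr(recon, "matrix", recon)
    e = getattr(encode, "matrix", encode)
    if r.shape[1] != e.shape[0] or r.shape[0] != e.shape[1]:
        raise ValueError(f"shapes do not compose: Recon {r.shape}, Encode {e.shape}")
    grid = getattr(recon, "grid", None) or getattr(encode, "grid", None)
    if full:
        mat = r @ e
        return SRFResult(srf_matrix=mat, srf_map=np.real(np.diag(mat)), grid=grid)
    diag = np.einsum("ij,ji->i", r, e)
    return SRFResult(srf_matrix=None, srf_map=np.real(diag), grid=grid)


def noise(recon, psi: Optional[np.ndarray] = None, full: bool = False) -> NoiseResult:
    """Noise matrix X = Recon @ Psi @ Recon^H and its map sqrt(diag X).

    ``psi`` is the (Hermitian PSD) noise covariance of the measurements;
    identity by default.  The map carries standard-deviation units.
    """
    r = getattr(recon, "matrix", recon)
    grid = getattr(recon, "grid", None)
    if psi is None:
        if full:
            x = r @ r.conj().T
            return NoiseResult(x, np.sqrt(np.clip(np.real(np.diag(x)), 0, None)), grid)
        diag = np.sum(np.abs(r) ** 2, axis=1)
        return NoiseResult(None, np.sqrt(diag), grid)
    psi = np.asarray(psi)
    if psi.shape != (r.shape[1], r.shape[1]):
        raise ValueError("psi must be N_meas x N_meas")
    evals = sla.eigvalsh(psi)
    if evals[0] < -1e-10 * max(evals[-1], 1.0):
        raise ValueError("psi must be positive semi-definite")
    rp = r @ psi
    if full:
        x = rp @ r.conj().T
        return NoiseResult(x, np.sqrt(np.clip(np.real(np.diag(x)), 0, None)), grid)
    diag = np.real(np.einsum("ij,ij->i", rp, r.conj()))
    return NoiseResult(None, np.sqrt(np.clip(diag, 0, None)), grid)


def spectrum(encode) -> np.ndarray:
    """Singular values of the encoding matrix, non-increasing."""
    e = getattr(encode, "matrix", encode)
    return sla.svdvals(e)


def condition_number(sigma: np.ndarray, truncation: Optional[int] = None) -> float:
    """kappa = sigma_max / smallest kept singular value."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size == 0 or sigma[0] <= 0:
        raise DegenerateInputError("spectrum is identically zero")
    kept = sigma if truncation is None else sigma[:truncation]
    kept = kept[kept > 0]
    if kept.size == 0:
        raise DegenerateInputError("no positive singular value kept")
    return float(sigma[0] / kept[-1])


def nmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized MSE: sum |a - b|^2 / sum |b|^2 (b is the reference)."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("nmse arguments must have equal length")
    denom = float(np.sum(np.abs(b) ** 2))
    if denom == 0:
        raise ValueError("nmse reference has zero norm")
    return float(np.sum(np.abs(a - b) ** 2) / denom)


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Plain mean squared error, mean |a - b|^2."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("mse arguments must have equal length")
    return float(np.mean(np.abs(a - b) ** 2))


def mse_zero(ref: np.ndarray) -> float:
    """MSE between the reference and a zero image: mean |ref|^2."""
    return float(np.mean(np.abs(np.asarray(ref)) ** 2))


def ideal_circular_ref(phantom, grid: Optional[ImageGrid] = None) -> np.ndarray:
    """Resolution-limited reference: inverse DFT of the phantom's DFT with
    spatial frequencies outside the circular k-space FOV (|k| <= mtx/2) zeroed.

    This is the best image any reconstruction from circularly-covered k-space
    can achieve; the residual against the phantom is the Delta-Res floor.
    """
    if isinstance(phantom, Phantom):
        grid = grid or phantom.grid
        values = phantom.values
    else:
        values = np.asarray(phantom)
        if grid is None:
            raise ValueError("grid required when passing a raw array")
    img = np.asarray(values).reshape(grid.shape)
    f = np.fft.fftshift(np.fft.fftn(img))
    axes = [np.arange(n) - n // 2 for n in grid.shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    rho2 = sum((m / (n / 2.0)) ** 2 for m, n in zip(mesh, grid.shape))
    f[rho2 > 1.0] = 0.0
    out = np.fft.ifftn(np.fft.ifftshift(f))
    if np.isrealobj(values):
        out = np.real(out)
    return out.ravel()


def _default_reg_grid() -> dict:
    return {
        "tsvd": np.logspace(-4, 0, 20),          # energy_keep values
        "tikhonov": np.logspace(-6, 5, 20),      # lambda_rel values
    }


def regularization_sweep(phantom: Phantom, traj: KSpaceTrajectory,
                         noise_levels, reg_grid: Optional[dict] = None,
                         seed: int = 0) -> pd.DataFrame:
    """tSVD-vs-Tikhonov regularization study on a forward-encoded phantom.

    For every (noise level, regularization method, regularization value) the
    phantom is forward-encoded, complex Gaussian noise is added in k-space,
    and the image is reconstructed from a single SVD of the encoding matrix.
    Returns a tidy table with columns (noise_level, reg_method, reg_value,
    kappa, mse_vs_phantom, mse_noise_only, nmse_vs_phantom).

    ``mse_noise_only`` is the MSE between the reconstruction of the pure
    noise and the resolution-limited ideal reference image.
    """
    grid = phantom.grid
    reg_grid = reg_grid or _default_reg_grid()
    enc = fourier_encode(traj, grid, precision="double")
    ref = grid.extract(ideal_circular_ref(phantom))
    truth = phantom.masked()
    u, s, vh = sla.svd(enc.matrix, full_matrices=False)
    v = vh.conj().T
    data0 = enc.matrix @ truth

    rows = []
    for i, level in enumerate(np.atleast_1d(noise_levels)):
        noise_vec = add_noise(np.zeros_like(data0), float(level), seed + i)
        coef_data = u.conj().T @ (data0 + noise_vec)
        coef_noise = u.conj().T @ noise_vec
        for method, values in reg_grid.items():
            for val in np.atleast_1d(values):
                if method == "tsvd":
                    spec_ = RegularizationSpec(method="tsvd", energy_keep=float(val))
                    rank = truncation_rank(s, spec_)
                    filt = np.zeros_like(s)
                    filt[:rank] = 1.0 / s[:rank]
                    kappa = float(s[0] / s[rank - 1])
                elif method == "tikhonov":
                    lam = float(val) * s[0]
                    filt = s / (s ** 2 + lam ** 2)
                    kappa = float(np.sqrt((s[0] ** 2 + lam ** 2)
                                          / (s[-1] ** 2 + lam ** 2)))
                else:
                    raise ValueError(f"unknown sweep method {method!r}")
                img = v @ (filt * coef_data)
                img_noise = v @ (filt * coef_noise)
                rows.append({
                    "noise_level": float(level),
                    "reg_method": method,
                    "reg_value": float(val),
                    "kappa": kappa,
                    "mse_vs_phantom": mse(img, truth),
                    "mse_noise_only": mse(img_noise, ref),
                    "nmse_vs_phantom": nmse(img, truth),
                })
    return pd.DataFrame(rows)
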