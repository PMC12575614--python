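"""Explicit pseudoinversion of the encoding matrix.

Five algebraic routes to the reconstruction operator Recon = Encode^+ :

* ``pinv_svd``            — (truncated) singular value decomposition of Encode
* ``pinv_qr``             — QR of Encode (Tikhonov via the row-augmented [E; lam*I])
* ``pinv_eig``            — eigendecomposition of the Gram matrix
* ``pinv_cholesky``       — Cholesky of the (Tikhonov-shifted) Gram matrix
* ``pinv_cholesky_block`` — same contract, right-looking blocked factorization

plus two routes that return the image without forming Recon
(``solve_direct``, ``solve_cg``) and the left/right normal-equation pair
(``choose_side``, ``pinv_right``).

Regularization is transparent: truncated SVD keeps the singular values
carrying a requested fraction of the spectral energy (or a target condition
number), Tikhonov adds ``lambda^2`` to the Gram diagonal with
``lambda = lambda_rel * sigma_max(Encode)``, and the two can be combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg as sla

from .encoding import (EncodeMatrix, GramMatrix, gram as build_gram,
                       largest_eigenvalue, sigma_max)
from .errors import (DegenerateRegularizationError, NotPositiveDefiniteError,
                     NumericalConsistencyError, SingularMatrixError)

#: column-block width for triangular solves against Encode^H (bounds peak memory)
SOLVE_BLOCK_COLS = 1024


@dataclass
class RegularizationSpec:
    """How the pseudoinversion is regularized.

    method      : 'none' | 'tsvd' | 'tikhonov' | 'both'
    energy_keep : for tSVD, keep the largest singular values carrying at least
                  this fraction of the total energy (sum of sigma^2 by default)
    cond_target : alternative tSVD rule — keep sigma >= sigma_max / cond_target
    lambda_rel  : Tikhonov lambda relative to sigma_max(Encode)
    energy_on   : 'sigma2' (default) or 'sigma' — which spectrum the energy
                  fraction is computed on
    """

    method: str = "none"
    energy_keep: Optional[float] = None
    cond_target: Optional[float] = None
    lambda_rel: float = 0.0
    energy_on: str = "sigma2"

    def __post_init__(self) -> None:
        if self.method not in ("none", "tsvd", "tikhonov", "both"):
            raise ValueError(f"unknown regularization method {self.method!r}")
        if self.energy_keep is not None and not 0 < self.energy_keep <= 1:
            raise ValueError("energy_keep must be in (0, 1]")
        if self.energy_keep is not None and self.cond_target is not None:
            raise ValueError("energy_keep and cond_target are mutually exclusive")
        if self.lambda_rel < 0:
            raise ValueError("lambda_rel must be >= 0")
        if self.energy_on not in ("sigma2", "sigma"):
            raise ValueError("energy_on must be 'sigma2' or 'sigma'")

    @property
    def truncates(self) -> bool:
        return self.method in ("tsvd", "both")

    @property
    def tikhonov(self) -> bool:
        return self.method in ("tikhonov", "both") and self.lambda_rel > 0


@dataclass
class ReconOperator:
    """Explicit N_unknown x N_meas reconstruction operator with provenance."""

    matrix: np.ndarray
    method: str
    reg: RegularizationSpec
    spectrum: Optional[np.ndarray] = None   # singular values of Encode, descending
    kappa: Optional[float] = None           # condition number after truncation
    grid: object = None                     # ImageGrid carried over from Encode
    n_species: int = 1

    @property
    def shape(self) -> tuple:
        return self.matrix.shape

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Reconstruct one or more data frames (last axis = frames)."""
        return self.matrix @ np.asarray(data)


def _as_array(encode) -> np.ndarray:
    return getattr(encode, "matrix", np.asarray(encode))


def _carry(encode) -> dict:
    if isinstance(encode, EncodeMatrix):
        return {"grid": encode.grid, "n_species": encode.n_species}
    return {}


def truncation_rank(sigma: np.ndarray, reg: RegularizationSpec) -> int:
    """Number of singular values kept under the spec's truncation rule.

    Energy rule: the smallest rank whose cumulative energy reaches
    ``energy_keep`` of the total (a value lying exactly on the threshold is
    kept).  Condition rule: keep sigma >= sigma_max / cond_target.
    """
    sigma = np.asarray(sigma, dtype=float)
    if reg.cond_target is not None:
        rank = int(np.sum(sigma >= sigma[0] / reg.cond_target))
    elif reg.energy_keep is not None:
        energy = sigma ** 2 if reg.energy_on == "sigma2" else sigma
        cum = np.cumsum(energy) / np.sum(energy)
        rank = int(np.searchsorted(cum, reg.energy_keep - 1e-15) + 1)
        rank = min(rank, sigma.size)
    else:
        rank = sigma.size
    rank = min(rank, int(np.sum(sigma > 0)))
    if rank == 0:
        raise DegenerateRegularizationError("truncation removed every singular value")
    return rank


def pinv_svd(encode, reg: Optional[RegularizationSpec] = None) -> ReconOperator:
    """Pseudoinverse via (truncated) SVD: Recon = V~ S~^-1 U~^H.

    Tikhonov (method 'tikhonov'/'both') is realized through the SVD filter
    factor sigma / (sigma^2 + lambda^2), equivalent to Eq.-(6)-style normal
    equations.
    """
    reg = reg or RegularizationSpec()
    e = _as_array(encode)
    u, s, vh = sla.svd(e, full_matrices=False)
    if s[0] == 0:
        raise DegenerateRegularizationError("encoding matrix is identically zero")
    rank = truncation_rank(s, reg) if reg.truncates else int(np.sum(s > 0))
    if rank == 0:
        raise DegenerateRegularizationError("encoding matrix has rank zero")
    s_kept = s[:rank]
    if reg.tikhonov:
        # shared power-method sigma_max so lambda matches the Gram-based routes
        lam = reg.lambda_rel * sigma_max(e)
        filt = s_kept / (s_kept ** 2 + lam ** 2)
    else:
        filt = 1.0 / s_kept
    recon = (vh[:rank].conj().T * filt) @ u[:, :rank].conj().T
    return ReconOperator(matrix=recon, method="svd", reg=reg, spectrum=s,
                         kappa=float(s[0] / s_kept[-1]), **_carry(encode))


def pinv_qr(encode, reg: Optional[RegularizationSpec] = None) -> ReconOperator:
    """Pseudoinverse via QR: Recon = R^-1 Q^H.

    Requires a tall (N_meas >= N_unknown) encoding matrix.  Tikhonov
    regularization factors the row-augmented matrix [E; lambda*I] and drops
    the identity-block columns of Q^H, which reproduces the Tikhonov normal
    equations exactly.
    """
    reg = reg or RegularizationSpec()
    e = _as_array(encode)
    m, n = e.shape
    if m < n:
        raise ValueError("pinv_qr requires a tall matrix (N_meas >= N_unknown); "
                         "use pinv_right for the underdetermined case")
    if reg.tikhonov:
        lam = reg.lambda_rel * sigma_max(e)
        aug = np.vstack([e, lam * np.eye(n, dtype=e.dtype)])
        q, r = sla.qr(aug, mode="economic")
        qh = q.conj().T[:, :m]  # drop the identity-block columns
    else:
        q, r = sla.qr(e, mode="economic")
        qh = q.conj().T
    diag = np.abs(np.diag(r))
    if np.any(diag <= max(m, n) * np.finfo(e.dtype).eps * diag.max()):
        raise SingularMatrixError(
            "R is numerically rank-deficient; add Tikhonov regularization")
    recon = sla.solve_triangular(r, qh, lower=False)
    return ReconOperator(matrix=recon, method="qr", reg=reg, **_carry(encode))


def _eig_of_gram(gm: GramMatrix) -> tuple:
    vals, vecs = sla.eigh(gm.matrix)
    lam_max = float(vals[-1])
    if lam_max <= 0:
        raise DegenerateRegularizationError("Gram matrix has no positive eigenvalue")
    if float(vals[0]) < -1e-6 * lam_max:
        raise NumericalConsistencyError(
            f"Gram matrix has a significantly negative eigenvalue ({vals[0]:.3e})")
    return vals[::-1].copy(), vecs[:, ::-1].copy()  # descending


def pinv_eig(gram: GramMatrix, encode, reg: Optional[RegularizationSpec] = None
             ) -> ReconOperator:
    """Pseudoinverse via eigendecomposition of the Gram matrix:
    Recon = P Lambda^-1 P^H E^H, with optional eigenvalue truncation and/or
    Tikhonov shift.

    If the Gram matrix was already built with a Tikhonov shift
    (``gram.lambda2 > 0``), no further shift is applied.
    """
    reg = reg or RegularizationSpec()
    e = _as_array(encode)
    vals, vecs = _eig_of_gram(gram)
    vals = np.clip(vals, 0.0, None)
    lam2 = gram.lambda2
    if reg.tikhonov and gram.lambda2 == 0:
        lam2 = (reg.lambda_rel ** 2) * largest_eigenvalue(gram.matrix)
        vals = vals + lam2
    sigma = np.sqrt(np.clip(vals - lam2, 0.0, None))  # spectrum of Encode
    if reg.truncates:
        rank = truncation_rank(np.sqrt(vals), reg)
    else:
        rank = int(np.sum(vals > 0))
    if rank == 0:
        raise DegenerateRegularizationError("eigenvalue truncation removed everything")
    p = vecs[:, :rank]
    inv_vals = 1.0 / vals[:rank]
    recon = (p * inv_vals) @ (p.conj().T @ e.conj().T)
    kappa = float(np.sqrt(vals[0] / vals[rank - 1]))
    return ReconOperator(matrix=recon, method="eig", reg=reg, spectrum=sigma,
                         kappa=kappa, **_carry(encode))


def _chol_recon(l_factor: np.ndarray, e: np.ndarray,
                block_cols: int = SOLVE_BLOCK_COLS) -> np.ndarray:
    """(L^-1)^H L^-1 E^H via two triangular solves, in column blocks of E^H."""
    n, m = l_factor.shape[0], e.shape[0]
    recon = np.empty((n, m), dtype=np.result_type(l_factor.dtype, e.dtype))
    eh = e.conj().T
    for start in range(0, m, block_cols):
        sl = slice(start, min(start + block_cols, m))
        y = sla.solve_triangular(l_factor, eh[:, sl], lower=True)
        recon[:, sl] = sla.solve_triangular(l_factor.conj().T, y, lower=False)
    return recon


def pinv_cholesky(gram: GramMatrix, encode,
                  reg: Optional[RegularizationSpec] = None) -> ReconOperator:
    """Pseudoinverse via Cholesky of the Gram matrix:
    Recon = (L^-1)^H L^-1 E^H (two triangular solves, no explicit L inverse)."""
    reg = reg or RegularizationSpec(method="tikhonov" if gram.lambda2 > 0 else "none")
    e = _as_array(encode)
    try:
        l_factor = sla.cholesky(gram.matrix, lower=True)
    except sla.LinAlgError as err:
        raise NotPositiveDefiniteError(
            "Cholesky factorization failed: the Gram matrix is not positive-"
            "definite; increase lambda_rel") from err
    recon = _chol_recon(l_factor, e)
    return ReconOperator(matrix=recon, method="chol", reg=reg, **_carry(encode))


def blocked_cholesky(matrix: np.ndarray, block: int) -> np.ndarray:
    """Right-looking blocked Cholesky (lower factor), sequential block sweep."""
    n = matrix.shape[0]
    if not 1 <= block <= n:
        raise ValueError(f"block must be in [1, {n}], got {block}")
    a = np.array(matrix, dtype=complex, copy=True)
    for start in range(0, n, block):
        end = min(start + block, n)
        try:
            a[start:end, start:end] = sla.cholesky(a[start:end, start:end], lower=True)
        except sla.LinAlgError as err:
            raise NotPositiveDefiniteError(
                "blocked Cholesky failed: the Gram matrix is not positive-"
                "definite; increase lambda_rel") from err
        ljj = a[start:end, start:end]
        if end < n:
            panel = sla.solve_triangular(ljj, a[end:, start:end].conj().T,
                                         lower=True).conj().T
            a[end:, start:end] = panel
            a[end:, end:] -= panel @ panel.conj().T
    return np.tril(a)


def pinv_cholesky_block(gram: GramMatrix, encode, block: int,
                        reg: Optional[RegularizationSpec] = None) -> ReconOperator:
    """Identical contract to :func:`pinv_cholesky`, computed with a
    right-looking blocked factorization (the memory-limited strategy)."""
    reg = reg or RegularizationSpec(method="tikhonov" if gram.lambda2 > 0 else "none")
    e = _as_array(encode)
    l_factor = blocked_cholesky(gram.matrix, block)
    recon = _chol_recon(l_factor, e)
    return ReconOperator(matrix=recon, method="chol_block", reg=reg, **_carry(encode))


def solve_direct(encode, data: np.ndarray,
                 reg: Optional[RegularizationSpec] = None) -> np.ndarray:
    """Least-squares / Tikhonov image without returning Recon.

    Solves (E^H E + lambda^2 I) x = E^H data through a Cholesky factorization
    (the regularized case) or a dense least-squares solve (unregularized).
    """
    reg = reg or RegularizationSpec()
    e = _as_array(encode)
    data = np.asarray(data)
    if reg.tikhonov:
        gm = build_gram(e, lambda_rel=reg.lambda_rel)
        try:
            c, low = sla.cho_factor(gm.matrix, lower=True)
        except sla.LinAlgError as err:
            raise NotPositiveDefiniteError(
                "direct solve failed; increase lambda_rel") from err
        return sla.cho_solve((c, low), e.conj().T @ data)
    x, *_ = sla.lstsq(e, data, lapack_driver="gelsd")
    return x


def solve_cg(encode_or_gram, data: np.ndarray, lambda_rel: float = 0.0,
             n_iter: int = 50, tol: float = 0.0, callback=None):
    """Conjugate gradients on the regularized normal equations
    (E^H E + lambda^2 I) x = E^H data, zero initialization.

    Given an encoding matrix, the Gram matrix is never formed (matrix-free
    application of E and E^H).  Given a :class:`GramMatrix`, ``data`` must
    already be the adjoint vector E^H data.  Returns ``(image, history)``
    where ``history`` is the relative residual norm per iteration;
    non-convergence is reported in the history, never raised.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if isinstance(encode_or_gram, GramMatrix):
        gm = encode_or_gram.matrix
        lam2 = encode_or_gram.lambda2
        if lambda_rel > 0 and lam2 == 0:
            lam2 = lambda_rel ** 2 * largest_eigenvalue(gm)

        def apply_a(x):
            return gm @ x + (lam2 - encode_or_gram.lambda2) * x
        b = np.asarray(data)
    else:
        e = _as_array(encode_or_gram)
        data = np.asarray(data)
        lam2 = 0.0
        if lambda_rel > 0:
            lam2 = (lambda_rel * sigma_max(e)) ** 2

        def apply_a(x):
            return e.conj().T @ (e @ x) + lam2 * x
        b = e.conj().T @ data

    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.real(np.vdot(r, r))
    b_norm = float(np.sqrt(np.real(np.vdot(b, b)))) or 1.0
    history = []
    for _ in range(n_iter):
        ap = apply_a(p)
        denom = np.real(np.vdot(p, ap))
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.real(np.vdot(r, r))
        history.append(float(np.sqrt(rs_new)) / b_norm)
        if callback is not None:
            callback(x.copy(), len(history))
        if tol > 0 and history[-1] <= tol:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, history


def choose_side(encode) -> str:
    """'left' (least-squares) for N_meas >= N_unknown, else 'right' (min-norm)."""
    e = _as_array(encode)
    return "left" if e.shape[0] >= e.shape[1] else "right"


def pinv_right(encode, reg: Optional[RegularizationSpec] = None) -> ReconOperator:
    """Right (minimum-norm) pseudoinverse via the Hermitian-transpose identity
    pinv_right(E) = (pinv_left(E^H))^H."""
    reg = reg or RegularizationSpec()
    e = _as_array(encode)
    left = pinv_svd(e.conj().T, reg)
    return ReconOperator(matrix=left.matrix.conj().T, method="right_" + left.method,
                         reg=reg, spectrum=left.spectrum, kappa=left.kappa,
                         **_carry(encode))
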