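"""scikit-learn style estimator wrapping the pseudoinverse reconstruction.

``fit`` factorizes the encoding matrix into an explicit reconstruction
operator; ``transform`` applies it to k-space data frames.  This mirrors the
workflow the method is built around: the operator depends only on the
trajectory/encoding model, is computed once (possibly before any data
exists), and is then reused across frames, time points or metabolites.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import EncodeMatrix, gram
from .inversion import (RegularizationSpec, choose_side, pinv_cholesky,
                        pinv_cholesky_block, pinv_eig, pinv_qr, pinv_right,
                        pinv_svd, solve_cg)


class PinvRecon(BaseEstimator, TransformerMixin):
    """MR image reconstruction by explicit pseudoinversion of the encoding matrix.

    Parameters
    ----------
    method : {'cholesky', 'svd', 'qr', 'eig', 'cholesky_block', 'cg'}
        Algebraic route to the pseudoinverse.  'cholesky' (the fastest dense
        route) is the default; 'cg' solves per-frame without forming Recon.
    lambda_rel : float
        Tikhonov regularization, lambda relative to sigma_max(Encode).
    energy_keep : float or None
        tSVD: keep singular values carrying this fraction of spectral energy.
    cond_target : float or None
        tSVD alternative: keep sigma >= sigma_max / cond_target.
    block : int or None
        Block size for the blocked Cholesky route.
    side : {'auto', 'left', 'right'}
        Normal-equation side; 'auto' picks left (least squares) for
        overdetermined and right (minimum norm) for underdetermined systems.
    cg_iter, cg_tol : conjugate-gradient controls (method='cg' only).

    Attributes
    ----------
    operator_ : ReconOperator (absent for method='cg')
    recon_matrix_ : ndarray, the explicit N_unknown x N_meas pseudoinverse
    spectrum_ : singular values of Encode when the route provides them
    kappa_ : condition number after truncation, when available
    n_meas_, n_unknown_ : problem dimensions
    """

    def __init__(self, method: str = "cholesky", lambda_rel: float = 1e-3,
                 energy_keep=None, cond_target=None, energy_on: str = "sigma2",
                 block=None, side: str = "auto", cg_iter: int = 50,
                 cg_tol: float = 0.0):
        self.method = method
        self.lambda_rel = lambda_rel
        self.energy_keep = energy_keep
        self.cond_target = cond_target
        self.energy_on = energy_on
        self.block = block
        self.side = side
        self.cg_iter = cg_iter
        self.cg_tol = cg_tol

    def _reg(self) -> RegularizationSpec:
        truncates = self.energy_keep is not None or self.cond_target is not None
        if truncates and self.lambda_rel > 0:
            method = "both"
        elif truncates:
            method = "tsvd"
        elif self.lambda_rel > 0:
            method = "tikhonov"
        else:
            method = "none"
        return RegularizationSpec(method=method, energy_keep=self.energy_keep,
                                  cond_target=self.cond_target,
                                  lambda_rel=self.lambda_rel,
                                  energy_on=self.energy_on)

    def fit(self, X, y=None):
        """Factorize the encoding matrix X (EncodeMatrix or ndarray)."""
        if self.method not in ("cholesky", "svd", "qr", "eig",
                               "cholesky_block", "cg"):
            raise ValueError(f"unknown method {self.method!r}")
        e = X.matrix if isinstance(X, EncodeMatrix) else np.asarray(X)
        self.n_meas_, self.n_unknown_ = e.shape
        reg = self._reg()
        self._grid = X.grid if isinstance(X, EncodeMatrix) else None
        if self.method == "cg":
            self._encode = X
            self.operator_ = None
            self.recon_matrix_ = None
            return self
        side = choose_side(e) if self.side == "auto" else self.side
        if side == "right":
            op = pinv_right(X, reg)
        elif self.method == "svd":
            op = pinv_svd(X, reg)
        elif self.method == "qr":
            op = pinv_qr(X, reg)
        else:
            gm = gram(e, lambda_rel=self.lambda_rel)
            if self.method == "eig":
                op = pinv_eig(gm, X, reg)
            elif self.method == "cholesky_block":
                block = self.block or max(1, e.shape[1] // 4)
                op = pinv_cholesky_block(gm, X, block, reg)
            else:
                op = pinv_cholesky(gm, X, reg)
        self.operator_ = op
        self.recon_matrix_ = op.matrix
        self.spectrum_ = op.spectrum
        self.kappa_ = op.kappa
        return self

    def transform(self, X) -> np.ndarray:
        """Reconstruct data frames X of shape (n_frames, N_meas) or (N_meas,)."""
        if not hasattr(self, "n_meas_"):
            raise RuntimeError("this PinvRecon instance is not fitted yet")
        data = np.asarray(X)
        single = data.ndim == 1
        frames = data[None, :] if single else data
        if frames.shape[1] != self.n_meas_:
            raise ValueError(f"data frames have length {frames.shape[1]}, "
                             f"expected N_meas = {self.n_meas_}")
        if self.method == "cg":
            images = np.stack([
                solve_cg(self._encode, f, lambda_rel=self.lambda_rel,
                         n_iter=self.cg_iter, tol=self.cg_tol)[0]
                for f in frames])
        else:
            images = (self.recon_matrix_ @ frames.T).T
        return images[0] if single else images

    def fit_transform(self, X, y=None, data=None):
        """Fit on the encoding matrix X and reconstruct ``data``."""
        if data is None:
            raise ValueError("fit_transform needs data= (k-space frames)")
        return self.fit(X).transform(data)
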