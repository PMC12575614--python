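import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pinvrecon as pr
from pinvrecon.errors import (DegenerateRegularizationError,
                              NotPositiveDefiniteError, SingularMatrixError)
from pinvrecon.inversion import RegularizationSpec, truncation_rank


def _random_complex(m, n, seed):
    g = np.random.default_rng(seed)
    return g.standard_normal((m, n)) + 1j * g.standard_normal((m, n))


class TestTruncation:
    def test_diag_energy_example(self):
        # sigma = (3, 1): sigma^2 energy 9/10 >= 0.8, keep only sigma = 3
        e = np.zeros((3, 2))
        e[0, 0], e[1, 1] = 3.0, 1.0
        op = pr.pinv_svd(e, RegularizationSpec(method="tsvd", energy_keep=0.8))
        expect = np.zeros((2, 3))
        expect[0, 0] = 1 / 3
        assert np.allclose(op.matrix, expect)
        assert op.kappa == 1.0

    def test_boundary_value_kept_on_tie(self):
        sigma = np.array([2.0, 2.0, 1.0])
        reg = RegularizationSpec(method="tsvd", energy_keep=8 / 9)
        assert truncation_rank(sigma, reg) == 2

    def test_cond_target_rule(self):
        sigma = np.array([10.0, 5.0, 1.0, 0.01])
        reg = RegularizationSpec(method="tsvd", cond_target=10.0)
        assert truncation_rank(sigma, reg) == 3

    def test_energy_keep_one_keeps_all(self):
        sigma = np.array([3.0, 2.0, 1.0])
        reg = RegularizationSpec(method="tsvd", energy_keep=1.0)
        assert truncation_rank(sigma, reg) == 3

    def test_mutually_exclusive_rules(self):
        with pytest.raises(ValueError):
            RegularizationSpec(method="tsvd", energy_keep=0.9, cond_target=10)


class TestSVDRoute:
    def test_full_rank_exact_inverse(self):
        e = _random_complex(12, 12, 0)
        op = pr.pinv_svd(e, RegularizationSpec(method="tsvd", energy_keep=1.0))
        assert np.linalg.norm(op.matrix @ e - np.eye(12)) < 1e-10

    def test_matches_normal_equation_oracle(self):
        e = _random_complex(30, 20, 1)
        oracle = np.linalg.solve(e.conj().T @ e, e.conj().T)
        op = pr.pinv_svd(e)
        assert np.linalg.norm(op.matrix - oracle) <= 1e-8 * np.linalg.norm(oracle)

    def test_spectrum_and_kappa(self):
        e = np.diag([3.0, 1.0])
        op = pr.pinv_svd(e)
        assert np.allclose(op.spectrum, [3.0, 1.0])
        assert op.kappa == 3.0

    def test_rank_zero_raises(self):
        with pytest.raises(DegenerateRegularizationError):
            pr.pinv_svd(np.zeros((4, 3)))


class TestQRRoute:
    def test_scalar(self):
        op = pr.pinv_qr(np.array([[2.0 + 0j]]))
        assert np.allclose(op.matrix, [[0.5]])

    def test_tikhonov_augmented_matches_normal_equations(self):
        e = _random_complex(30, 20, 2)
        reg = RegularizationSpec(method="tikhonov", lambda_rel=1e-2)
        lam = 1e-2 * pr.sigma_max(e)
        oracle = np.linalg.solve(e.conj().T @ e + lam ** 2 * np.eye(20), e.conj().T)
        op = pr.pinv_qr(e, reg)
        assert np.linalg.norm(op.matrix - oracle) <= 1e-10 * np.linalg.norm(oracle)

    def test_rank_deficient_without_reg_raises(self):
        e = np.ones((5, 3), dtype=complex)
        with pytest.raises(SingularMatrixError):
            pr.pinv_qr(e)

    def test_wide_matrix_rejected(self):
        with pytest.raises(ValueError):
            pr.pinv_qr(_random_complex(3, 5, 0))


class TestEigRoute:
    def test_diag_eigenvalues_are_squared_singular_values(self):
        e = np.diag([3.0, 1.0]).astype(complex)
        op = pr.pinv_eig(pr.gram(e, 0.0), e)
        assert np.allclose(sorted(op.spectrum, reverse=True), [3.0, 1.0])

    def test_large_lambda_scalar_limit(self):
        # scalar E = 2: Recon = 2/(4 + lam^2) -> 2/lam^2 for large lambda
        e = np.array([[2.0 + 0j]])
        reg = RegularizationSpec(method="tikhonov", lambda_rel=100.0)
        gm = pr.gram(e, 100.0)
        op = pr.pinv_eig(gm, e, reg)
        lam2 = gm.lambda2
        assert np.isclose(op.matrix[0, 0].real, 2 / (4 + lam2), rtol=1e-10)

    def test_matches_svd_route(self):
        e = _random_complex(30, 20, 3)
        reg = RegularizationSpec(method="tikhonov", lambda_rel=1e-3)
        a = pr.pinv_svd(e, reg).matrix
        b = pr.pinv_eig(pr.gram(e, 1e-3), e, reg).matrix
        assert np.linalg.norm(a - b) <= 1e-8 * np.linalg.norm(a)


class TestCholeskyRoutes:
    def test_scalar_with_shift(self):
        # E = 2, lambda^2 = 1: G = 5, Recon = 2/5
        e = np.array([[2.0 + 0j]])
        gm = pr.GramMatrix(matrix=np.array([[5.0 + 0j]]), lambda2=1.0)
        op = pr.pinv_cholesky(gm, e)
        assert np.allclose(op.matrix, [[0.4]])

    def test_matches_explicit_inverse_oracle(self):
        e = _random_complex(40, 25, 4)
        gm = pr.gram(e, 1e-3)
        oracle = np.linalg.inv(gm.matrix) @ e.conj().T
        op = pr.pinv_cholesky(gm, e)
        assert np.linalg.norm(op.matrix - oracle) <= 1e-10 * np.linalg.norm(oracle)

    def test_not_positive_definite_raises(self):
        e = np.ones((3, 2), dtype=complex)
        gm = pr.GramMatrix(matrix=np.array([[1.0, 2.0], [2.0, 1.0]], dtype=complex))
        with pytest.raises(NotPositiveDefiniteError, match="lambda_rel"):
            pr.pinv_cholesky(gm, e)

    @pytest.mark.parametrize("block", [1, 7, 20])
    def test_blocked_matches_unblocked(self, block):
        e = _random_complex(30, 20, 5)
        gm = pr.gram(e, 1e-3)
        a = pr.pinv_cholesky(gm, e).matrix
        b = pr.pinv_cholesky_block(gm, e, block).matrix
        assert np.linalg.norm(a - b) <= 1e-10 * np.linalg.norm(a)

    def test_lower_triangular_positive_diagonal(self):
        from pinvrecon.inversion import blocked_cholesky
        e = _random_complex(25, 15, 6)
        gm = pr.gram(e, 1e-2)
        l_factor = blocked_cholesky(gm.matrix, 4)
        assert np.allclose(l_factor, np.tril(l_factor))
        assert np.all(np.real(np.diag(l_factor)) > 0)
        assert np.allclose(l_factor @ l_factor.conj().T, gm.matrix,
                           atol=1e-10 * np.abs(gm.matrix).max())


class TestDirectAndCG:
    def test_direct_matches_cholesky(self):
        e = _random_complex(30, 20, 7)
        d = _random_complex(30, 1, 8).ravel()
        reg = RegularizationSpec(method="tikhonov", lambda_rel=1e-3)
        gm = pr.gram(e, 1e-3)
        ref = pr.pinv_cholesky(gm, e, reg).matrix @ d
        x = pr.solve_direct(e, d, reg)
        assert np.linalg.norm(x - ref) <= 1e-10 * np.linalg.norm(ref)

    def test_direct_zero_data(self):
        e = _random_complex(10, 6, 9)
        assert np.allclose(pr.solve_direct(e, np.zeros(10, dtype=complex)), 0.0)

    def test_direct_orthogonal_case(self, cart16):
        grid, traj, enc = cart16
        d = _random_complex(256, 1, 10).ravel()
        x = pr.solve_direct(enc.matrix, d)
        assert np.allclose(x, enc.matrix.conj().T @ d / 256, atol=1e-10)

    def test_cg_finite_termination_2x2(self):
        a = np.array([[3.0, 1.0], [1.0, 2.0]], dtype=complex)
        gm = pr.GramMatrix(matrix=a)
        b = np.array([1.0, 1.0], dtype=complex)
        x, hist = pr.solve_cg(gm, b, n_iter=2)
        assert np.allclose(a @ x, b, atol=1e-12)
        assert len(hist) <= 2

    def test_cg_matches_cholesky(self):
        e = _random_complex(30, 20, 11)
        d = _random_complex(30, 1, 12).ravel()
        reg = RegularizationSpec(method="tikhonov", lambda_rel=1e-2)
        ref = pr.pinv_cholesky(pr.gram(e, 1e-2), e, reg).matrix @ d
        x, hist = pr.solve_cg(e, d, lambda_rel=1e-2, n_iter=300, tol=1e-14)
        assert np.linalg.norm(x - ref) <= 1e-8 * np.linalg.norm(ref)

    def test_cg_residual_history_decreases_overall(self):
        e = _random_complex(30, 20, 13)
        d = _random_complex(30, 1, 14).ravel()
        _, hist = pr.solve_cg(e, d, lambda_rel=1e-2, n_iter=50)
        assert hist[-1] < hist[0]


class TestSides:
    def test_row_unit_case(self):
        e = np.array([[1.0, 0.0]])
        op = pr.pinv_right(e)
        assert np.allclose(op.matrix, [[1.0], [0.0]])

    def test_min_norm_solution(self):
        e = _random_complex(10, 25, 15)
        d = _random_complex(10, 1, 16).ravel()
        x = pr.pinv_right(e).matrix @ d
        assert np.linalg.norm(e @ x - d) <= 1e-8 * np.linalg.norm(d)
        # orthogonal to null(E): x must lie in the row space
        _, _, vh = np.linalg.svd(e)
        null_basis = vh[10:]
        assert np.abs(null_basis @ x).max() < 1e-10

    def test_transpose_identity(self):
        e = _random_complex(10, 25, 17)
        right = pr.pinv_right(e).matrix
        left_of_h = pr.pinv_svd(e.conj().T).matrix
        assert np.linalg.norm(right - left_of_h.conj().T) \
            <= 1e-12 * np.linalg.norm(right)

    def test_choose_side(self):
        assert pr.choose_side(np.zeros((5, 3))) == "left"
        assert pr.choose_side(np.zeros((3, 5))) == "right"
        assert pr.choose_side(np.zeros((4, 4))) == "left"


class TestMoorePenroseProperties:
    @pytest.mark.parametrize("shape,seed", [((40, 25), 21), ((25, 25), 22),
                                            ((15, 25), 23)])
    def test_axioms(self, shape, seed):
        e = _random_complex(*shape, seed)
        if shape[0] >= shape[1]:
            op = pr.pinv_svd(e)
        else:
            op = pr.pinv_right(e)
        r = op.matrix
        assert np.linalg.norm(e @ r @ e - e) <= 1e-8 * np.linalg.norm(e)
        assert np.linalg.norm(r @ e @ r - r) <= 1e-8 * np.linalg.norm(r)


class TestRegularizationLimits:
    def test_conjugate_phase_limit_and_zero_image(self, spiral32):
        grid, traj, phantom, enc = spiral32
        data = enc.matrix @ phantom.masked()
        adj = enc.matrix.conj().T @ data
        norms = []
        for lr in [1.0, 10.0, 1e3]:
            reg = RegularizationSpec(method="tikhonov", lambda_rel=lr)
            img = pr.pinv_svd(enc, reg).matrix @ data
            norms.append(np.linalg.norm(img))
            if lr == 1e3:
                corr = np.abs(np.vdot(img, adj)) / (
                    np.linalg.norm(img) * np.linalg.norm(adj))
                assert corr > 0.999
        assert norms[0] > norms[1] > norms[2]


@settings(deadline=None, max_examples=20, derandomize=True)
@given(m=st.integers(5, 30), n=st.integers(2, 20), seed=st.integers(0, 2**16))
def test_pinv_consistency_property(m, n, seed):
    """SVD route equals the independent numpy pseudoinverse on random
    full-rank matrices of either orientation."""
    e = _random_complex(m, n, seed)
    op = pr.pinv_svd(e) if m >= n else pr.pinv_right(e)
    oracle = np.linalg.pinv(e)
    assert np.linalg.norm(op.matrix - oracle) <= 1e-8 * np.linalg.norm(oracle)
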