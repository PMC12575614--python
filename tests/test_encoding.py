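import numpy as np
import pytest

import pinvrecon as pr
from pinvrecon.errors import ResourceLimitError


class TestFourierEncode:
    def test_unit_modulus_entries(self):
        traj = pr.make_spiral(16, 4, 40)
        grid = pr.make_grid((16, 16))
        e = pr.fourier_encode(traj, grid, precision="double").matrix
        assert np.allclose(np.abs(e), 1.0, atol=1e-12)

    def test_8x8_scaled_unitary(self):
        grid, traj = pr.make_cartesian((8, 8))
        e = pr.fourier_encode(traj, grid, precision="double").matrix / np.sqrt(64)
        assert np.linalg.norm(e.conj().T @ e - np.eye(64)) < 1e-10

    def test_dimension_mismatch(self):
        traj = pr.make_spiral(8, 2, 20)
        with pytest.raises(ValueError):
            pr.fourier_encode(traj, pr.make_grid((8,)))

    def test_memory_cap(self):
        traj = pr.make_spiral(64, 8, 512)
        grid = pr.make_grid((64, 64))
        with pytest.raises(ResourceLimitError, match="block-wise"):
            pr.fourier_encode(traj, grid, memory_cap=1024)

    def test_single_precision_storage(self):
        grid, traj = pr.make_cartesian((4, 4))
        assert pr.fourier_encode(traj, grid).matrix.dtype == np.complex64


class TestBuildEncode:
    def test_identity_factors_reduce_to_fourier(self):
        traj = pr.make_spiral(12, 3, 30)
        grid = pr.make_grid((12, 12))
        a = pr.build_encode(traj, grid, pr.EncodingFactors(), precision="double")
        b = pr.fourier_encode(traj, grid, precision="double")
        assert np.array_equal(a.matrix, b.matrix)

    def test_uniform_coil_is_scalar_factor(self):
        traj = pr.make_spiral(12, 3, 30)
        grid = pr.make_grid((12, 12))
        c = 0.7 - 0.2j
        fac = pr.EncodingFactors(coil_maps=np.full((1, grid.n_full), c))
        a = pr.build_encode(traj, grid, fac, precision="double")
        b = pr.fourier_encode(traj, grid, precision="double")
        assert np.allclose(a.matrix, c * b.matrix, atol=1e-12)

    def test_b0_phase_single_voxel(self):
        # dB0 = 2 pi 10 rad/s over t = 0.05 s gives phase pi, i.e. factor -1
        traj = pr.KSpaceTrajectory(coords=np.zeros((1, 2)), times=[0.05],
                                   interleave=[0], dim=2)
        mask = np.zeros(16, dtype=bool)
        mask[0] = True
        grid = pr.ImageGrid(shape=(4, 4), mask=mask)
        fac = pr.EncodingFactors(b0_map=np.full(16, 2 * np.pi * 10.0))
        e = pr.build_encode(traj, grid, fac, precision="double").matrix
        base = pr.fourier_encode(traj, grid, precision="double").matrix
        assert np.allclose(e, -base, atol=1e-12)

    def test_b0_without_times_rejected(self):
        grid, traj = pr.make_cartesian((4, 4))
        fac = pr.EncodingFactors(b0_map=np.ones(16))
        with pytest.raises(ValueError, match="times"):
            pr.build_encode(traj, grid, fac)

    def test_te_without_shifts_rejected(self):
        grid, traj = pr.make_cartesian((4, 4))
        with pytest.raises(ValueError, match="species_shifts"):
            pr.build_encode(traj, grid,
                            pr.EncodingFactors(echo_times=np.array([0.0, 1e-3])))

    def test_row_and_column_dimensions(self):
        traj = pr.make_spiral(8, 2, 20)
        grid = pr.make_grid((8, 8))
        fac = pr.EncodingFactors(coil_maps=pr.sim_coil_maps(grid, 3),
                                 species_shifts=np.array([0.0, -100.0]),
                                 echo_times=np.array([0.0, 1e-3]))
        enc = pr.build_encode(traj, grid, fac, precision="double")
        assert enc.shape == (3 * 2 * traj.n_samples, 2 * grid.n_voxels)


class TestGram:
    def test_scalar_examples(self):
        e = np.array([[2.0 + 0j]])
        assert pr.gram(e, 0.0).matrix[0, 0] == 4.0
        # lambda = 0.5 * sigma_max = 1, so G = 4 + 1
        g = pr.gram(e, 0.5)
        assert np.isclose(g.matrix[0, 0], 5.0, rtol=1e-6)

    def test_hermitian_after_symmetrization(self, rng):
        e = rng.standard_normal((20, 12)) + 1j * rng.standard_normal((20, 12))
        g = pr.gram(e, 1e-2).matrix
        assert np.linalg.norm(g - g.conj().T) == 0.0

    def test_eigenvalues_equal_squared_singular_values(self):
        # Gram spectrum == sigma(Encode)^2 on a 32^2 case
        traj = pr.make_spiral(32, 8, 140)
        grid = pr.circular_mask(pr.make_grid((32, 32)), 1.0)
        enc = pr.fourier_encode(traj, grid, precision="double")
        g = pr.gram(enc, 0.0)
        evals = np.linalg.eigvalsh(g.matrix)[::-1]
        s2 = pr.spectrum(enc) ** 2
        assert np.allclose(evals, s2, rtol=1e-8, atol=1e-8 * s2[0])

    def test_masked_gram_is_principal_submatrix(self):
        grid = pr.make_grid((8, 8))
        masked = pr.circular_mask(grid, 1.0)
        traj = pr.make_spiral(8, 2, 40)
        gf = pr.gram(pr.fourier_encode(traj, grid, precision="double"), 0.0).matrix
        gm = pr.gram(pr.fourier_encode(traj, masked, precision="double"), 0.0).matrix
        sub = gf[np.ix_(masked.mask, masked.mask)]
        # the masked Encode is an exact column subset; the Gram entries agree
        # up to the accumulation order of the matrix product
        assert np.allclose(gm, sub, atol=1e-13 * np.abs(sub).max())


class TestCoilwise:
    def test_single_unit_coil_matches_plain_gram(self):
        traj = pr.make_spiral(8, 2, 30)
        grid = pr.make_grid((8, 8))
        maps = np.ones((1, grid.n_full), dtype=complex)
        a = pr.coilwise_gram(traj, grid, maps, 0.0).matrix
        b = pr.gram(pr.fourier_encode(traj, grid, precision="double"), 0.0).matrix
        assert np.allclose(a, b, atol=1e-12 * np.abs(b).max())

    @pytest.mark.parametrize("n_coils", [1, 2, 3, 4])
    def test_matches_stacked_gram(self, n_coils):
        traj = pr.make_spiral(16, 4, 70)
        grid = pr.circular_mask(pr.make_grid((16, 16)), 1.0)
        maps = pr.sim_coil_maps(grid, n_coils)
        enc = pr.build_encode(traj, grid, pr.EncodingFactors(coil_maps=maps),
                              precision="double")
        a = pr.coilwise_gram(traj, grid, maps, 1e-3).matrix
        b = pr.gram(enc, 1e-3).matrix
        assert np.linalg.norm(a - b) <= 1e-10 * np.linalg.norm(b)

    def test_adjoint_matches_and_zero_data(self):
        traj = pr.make_spiral(12, 3, 40)
        grid = pr.make_grid((12, 12))
        maps = pr.sim_coil_maps(grid, 3)
        enc = pr.build_encode(traj, grid, pr.EncodingFactors(coil_maps=maps),
                              precision="double")
        data = np.random.default_rng(2).standard_normal(enc.n_meas) + 0j
        a = pr.coilwise_adjoint(traj, grid, maps, data)
        b = enc.matrix.conj().T @ data
        assert np.allclose(a, b, atol=1e-10 * np.abs(b).max())
        assert np.all(pr.coilwise_adjoint(traj, grid, maps,
                                          np.zeros(enc.n_meas)) == 0)

    def test_adjoint_wrong_length(self):
        traj = pr.make_spiral(8, 2, 20)
        grid = pr.make_grid((8, 8))
        maps = pr.sim_coil_maps(grid, 2)
        with pytest.raises(ValueError):
            pr.coilwise_adjoint(traj, grid, maps, np.zeros(7))


class TestSubsetRows:
    def test_full_selector_is_identity(self):
        traj = pr.make_radial(8, 4)
        grid = pr.make_grid((8, 8))
        enc = pr.fourier_encode(traj, grid, precision="double")
        sub = pr.subset_rows(enc, np.arange(traj.n_samples))
        assert np.array_equal(sub.matrix, enc.matrix)

    def test_half_the_spokes_halves_n_meas(self):
        traj = pr.make_radial(8, 8)
        grid = pr.make_grid((8, 8))
        enc = pr.fourier_encode(traj, grid, precision="double")
        sel = np.isin(traj.interleave, np.arange(4))
        assert pr.subset_rows(enc, sel).n_meas == enc.n_meas // 2

    def test_r2_cartesian_keeps_every_other_line(self):
        grid, traj = pr.make_cartesian((8, 8))
        keep = traj.coords[:, 0] % 2 == 0
        enc = pr.fourier_encode(traj, grid, precision="double")
        sub = pr.subset_rows(enc, keep)
        assert sub.n_meas == enc.n_meas // 2
        assert np.array_equal(sub.matrix, enc.matrix[keep])

    def test_subset_replicates_across_coils(self):
        traj = pr.make_radial(8, 4)
        grid = pr.make_grid((8, 8))
        maps = pr.sim_coil_maps(grid, 2)
        enc = pr.build_encode(traj, grid, pr.EncodingFactors(coil_maps=maps),
                              precision="double")
        sub = enc.subset_rows(np.arange(8))  # first 8 k-samples of each coil
        n_k = traj.n_samples
        expect = np.vstack([enc.matrix[:8], enc.matrix[n_k:n_k + 8]])
        assert np.array_equal(sub.matrix, expect)

    def test_empty_selection_rejected(self):
        traj = pr.make_radial(8, 4)
        grid = pr.make_grid((8, 8))
        enc = pr.fourier_encode(traj, grid, precision="double")
        with pytest.raises(ValueError):
            pr.subset_rows(enc, np.array([], dtype=int))
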