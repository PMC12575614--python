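# pinvrecon

MR image reconstruction by **explicit pseudoinversion of the encoding
matrix** (Pinv-Recon): a library and CLI for assembling dense encoding
matrices from arbitrary k-space trajectories and generalized encoding
physics, inverting them through several algebraic routes with transparent
regularization, and deriving the image-quality metrics that only an explicit
reconstruction operator provides.

## The problem

MRI acquisition is a linear map from the unknown image to the measured
k-space samples,

```
data = Encode @ image,        Encode[i_k, i_r] = exp(+j 2π k_ik · r_ir)
```

optionally multiplied by receive-coil sensitivities, chemical-shift/echo-time
phases `exp(j ΔCS·TE)`, off-resonance accrual `exp(j ΔB0(r)·t_k)`, and
coordinate substitutions for gradient nonlinearity and rigid motion.
Reconstruction solves the inverse problem by explicitly forming

```
Recon = Encode⁺ = (Encodeᴴ Encode + λ²I)⁻¹ Encodeᴴ,     image = Recon @ data
```

via SVD, QR of the row-augmented `[E; λI]`, eigendecomposition or (blocked)
Cholesky factorization of the Gram matrix, with truncated-SVD and/or Tikhonov
(`λ = lambda_rel · σ_max`) regularization. Materializing `Recon` buys what
iterative solvers cannot offer directly: the spatial response function
`SRF = Recon @ Encode` (identity is ideal), the propagated noise covariance
`X = Recon Ψ Reconᴴ`, operator reuse across frames/metabolites/time points,
and data-agnostic precomputation for real-time reconstruction during
acquisition. The intended users are MR-physics researchers working at small
to medium matrix sizes (non-Cartesian, hyperpolarized, multi-nuclear,
low-field) where the dense inversion is affordable and its flexibility wins.

Everything is testable offline: a built-in synthetic module provides the
Shepp-Logan phantom evaluated analytically on arbitrary (masked,
overdiscretized) grids, parametric coil/B0/warp/species maps, forward
simulation and a seeded complex-Gaussian noise model.

## Worked example

```python
import numpy as np
import pinvrecon as pr

# 32x32 grid masked to the circular FOV, 8-arm Archimedean spiral
grid = pr.circular_mask(pr.make_grid((32, 32)), 1.0)
traj = pr.make_spiral(32, 8, 160)
phantom = pr.shepp_logan(grid)

# forward-encode and add complex Gaussian noise in k-space
enc = pr.fourier_encode(traj, grid, precision="double")
data = pr.add_noise(enc.matrix @ phantom.masked(), 0.1, seed=7)

# Cholesky-based pseudoinverse with Tikhonov lambda = 1e-3 * sigma_max
est = pr.PinvRecon(method="cholesky", lambda_rel=1e-3).fit(enc)
image = est.transform(data)

print("encode matrix:", enc.shape)
print("reconstruction NMSE:", round(pr.nmse(image, phantom.masked()), 4))

srf = pr.srf(est.operator_, enc)
noise = pr.noise(est.operator_)
print("mean SRF:", round(srf.srf_map.mean(), 4))
print("noise amplification (min/max):",
      round(noise.noise_map.min(), 4), round(noise.noise_map.max(), 4))
```

Output:

```
encode matrix: (1280, 793)
reconstruction NMSE: 0.0658
mean SRF: 0.8784
noise amplification (min/max): 0.1279 0.74
```

The encode matrix maps 793 in-FOV voxels to 1280 spiral samples. The NMSE of
~0.07 against the phantom is dominated by the circular k-space coverage (the
resolution floor), not by the added noise; the SRF map says a voxel's signal
is on average ~88% represented in the reconstruction at this regularization
(Tikhonov trades a little resolution for noise suppression), and the noise
map shows the spatially varying noise amplification (standard-deviation
units per unit k-space noise) that only the explicit operator makes
computable.

The same objects drive the CLI:

```
pinvrecon traj --type spiral --mtx 64 --arms 8 --out traj.h5
pinvrecon sim --traj-file traj.h5 --mask 1.0 --noise 0.1 --seed 7 --out sim.h5
pinvrecon encode --traj-file sim.h5 --precision double --out enc.h5
pinvrecon invert --enc enc.h5 --method chol --lambda-rel 1e-3 --out recon.h5
pinvrecon metrics --recon recon.h5 --enc enc.h5 --out metrics.h5
```

plus `pinvrecon sweep` (tSVD-vs-Tikhonov regularization study as CSV),
`pinvrecon bench` (timing/accuracy harness) and `pinvrecon run --config
job.yaml` for full config-driven jobs with HDF5/NIfTI output.

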