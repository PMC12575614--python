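# Methods

## The reconstruction model

MR acquisition is modeled as a linear forward map from the unknown image to
the measured k-space samples,

    data = Encode @ image,

where `Encode` is a dense complex matrix with one row per measurement and one
column per unknown. In the plain gradient-encoding case each entry is the
Fourier kernel

    Encode[i_k, i_r] = exp(+j 2π k_{i_k} · r_{i_r}),

with k in cycles/FOV and r in normalized FOV units, so `k · r` is a
dimensionless number of phase turns. Reconstruction inverts the map
explicitly: `image = Recon @ data` with `Recon = Encode⁺`, the (regularized)
Moore–Penrose pseudoinverse. Because `Recon` is materialized, the spatial
response function `SRF = Recon @ Encode` and the propagated noise covariance
`X = Recon @ Ψ @ Reconᴴ` are single matrix products away, and the operator
can be precomputed from the trajectory alone and reused across frames.

### Coordinate conventions

* Pixel `i` along an axis of size `N` sits at `(i − N/2)/N`, so the FOV is
  `[−0.5, 0.5)` and Cartesian sampling with integer `k ∈ [−N/2, N/2)` makes
  `Encode` an exact scaled-orthogonal DFT matrix (`Eᴴ E = N_r I`). The
  forward kernel carries the `+j` sign; the adjoint/inverse carries the
  conjugate.
* An overdiscretized grid keeps the same FOV with `overdisc·N` points per
  axis (spacing `1/(overdisc·N)`).
* Circular masks keep voxels with Euclidean radius strictly below
  `diameter/2`; on a square grid with unit diameter this retains ≈ π/4 of
  the voxels (78.4% on a 128² grid). Exact lattice counts depend on this
  tie-breaking convention; the strict-inequality rule is used throughout.

### Generalized encoding

Additional physics enters as multiplicative factors or coordinate
substitutions, preserving linearity:

* receive-coil sensitivity `Coil_c(r)` (rows replicated per coil, coil
  outermost in the row ordering),
* chemical-shift/echo-time phase `exp(j ΔCS_s · TE_e)` (species outermost in
  the column ordering),
* off-resonance phase accrual `exp(j ΔB0(r) · t_k)`,
* gradient nonlinearity as a spatial warp `r → r'` (mathematically equivalent
  to perturbing `k`, but avoiding an `N_k × N_r × d` tensor),
* off-center positioning / rigid motion as `r → Rot(t) r + Δr(t)`.

When a constant shift or motion moves evaluation points off the grid, coil
maps stored on the grid are evaluated by linear interpolation with
nearest-value extrapolation; the simulators' parametric forms are exact at
any coordinate, so tests of analytic properties use those directly.

## Inversion routes and regularization

Five algebraic routes produce the same regularized operator (double
precision, identical λ):

* SVD of `Encode` with the filter `σ/(σ² + λ²)` and optional truncation,
* QR of the row-augmented `[E; λI]` (dropping the identity-block columns of
  `Qᴴ`), which reproduces the Tikhonov normal equations exactly,
* eigendecomposition of the Gram matrix `Eᴴ E + λ²I`,
* Cholesky of the Gram matrix with two triangular solves against `Eᴴ`
  (applied in 1024-column blocks to bound peak memory; no explicit `L⁻¹`),
* a right-looking blocked Cholesky sweep for the memory-limited setting
  (handles non-divisor block sizes).

Tikhonov strength is specified as `lambda_rel = λ/σ_max(Encode)`. σ_max is
estimated once by a 20-iteration seeded power method on the symmetrized Gram
matrix (tolerance 1e-6) and the same estimate feeds every route, so
cross-method comparisons are not contaminated by differing λ. tSVD keeps the
smallest rank whose cumulative energy reaches `energy_keep`; energy defaults
to σ² (the conventional spectral energy) with σ selectable, and a value
exactly on the threshold is kept. A `cond_target` rule (keep
`σ ≥ σ_max/κ_target`) is the alternative truncation criterion. Underdetermined
systems use the right pseudoinverse via the Hermitian-transpose identity
`E⁺ = ((Eᴴ)⁺)ᴴ`, giving the minimum-norm solution; ties go to the left side.

The conjugate-gradient route solves `(EᴴE + λ²I)x = Eᴴd` matrix-free with
zero initialization and the standard Hestenes–Stiefel recurrence, no
preconditioner; non-convergence is reported in the residual history rather
than raised. `solve_direct` obtains the image through a Cholesky solve (or
dense least squares when unregularized) without returning `Recon`.

All factorizations are delegated to LAPACK via `scipy.linalg`; the blocked
Cholesky sweep, the CG recurrence, the encoding assembly and the coil-wise
Gram accumulation are implemented in this package.

### Numerical choices

* Encoding matrices are stored in single precision by default (the realistic
  deployment choice); every validation path runs in double.
* Gram matrices are explicitly symmetrized, `(G + Gᴴ)/2`, guarding Cholesky
  against rounding asymmetry; an eigenvalue below `−1e-6·λ_max` raises a
  consistency error rather than being clipped silently.
* A predicted-memory cap (default 16 GiB) on dense encode assembly raises a
  hard error naming the masking / coil-wise / block-wise remedies instead of
  swapping silently.
* Degenerate situations (empty masks, rank-zero truncation, indefinite Gram
  without regularization) raise typed exceptions.

## Synthetic data

The generator provides everything the tests and the acceptance script
consume; no external data are read.

* **Phantom** — the modified (contrast-enhanced) 10-ellipse Shepp-Logan
  table evaluated analytically at arbitrary coordinates, intensities in
  [0, 1] (0.2 at the center). Analytic evaluation, rather than a fixed-size
  raster, is required for masked and overdiscretized grids.
* **Coil maps** — Gaussian magnitude lobes (width 0.5 FOV by default)
  centered on the FOV boundary at equal azimuths with a linear phase along
  each coil's radial axis, optionally root-sum-of-squares normalized. This
  is a parametric surrogate for maps estimated from data; it reproduces the
  properties that matter for encoding (smoothness, spatial distinctness,
  complex phase) but not coil coupling or Biot–Savart field structure.
* **Off-resonance** — a low-order polynomial (quadratic bowl + linear ramp),
  zero mean over the mask, scaled to a peak magnitude in rad/s. The default
  test condition uses a 2π·300 rad/s peak, a typical 3 T air–tissue scale.
* **Gradient nonlinearity** — barrel distortion `r → r(1 + a‖r‖²)`;
  `a ≤ 0.4` keeps the FOV inside `[−0.6, 0.6)`.
* **Chemical shift** — two species with disjoint elliptical supports,
  shifts {0, −2π·440} rad/s (water/fat at 3 T) and echo times {0, 1.14 ms}
  (in/opposed phase) in the two-echo tests.
* **Noise** — `data + level·(g₁ + j·g₂/2)` with i.i.d. standard normal
  draws, reproducible from a seed. The asymmetric imaginary scale is the
  literal reading of the originating expression; a `symmetric` switch
  provides `level·(g₁ + j·g₂)/2`. No noise-dependent result in the package
  depends on the choice.

What the generator does not emulate: relaxation decay, Bloch dynamics,
realistic coil coupling, gradient-waveform constraints (spirals are
slew-unconstrained Archimedean arms with `mtx/(2·n_arms)` turns, radius
linear in the arc parameter), and scanner raw-data quirks. Passing tests
therefore demonstrate the algebra and the encoding model, not robustness to
physics the simulator omits.

## Workflows

* **Operator reuse** — one `Recon`, many frames, a single matrix-matrix
  product.
* **Separable Z** — a uniformly sampled Z axis is decoupled by an exact
  inverse DFT (implemented as the small explicit adjoint, identical to an
  FFT for this sampling), then one shared in-plane operator serves every
  slice.
* **Per-line SENSE** — with a fully sampled readout axis, each readout
  position yields a small `(coils × acquired-lines) × N_y` system that is
  pseudoinverted independently.
* **Two-pass masking** — circular-FOV pass, then a threshold mask (default
  0.1 of the peak magnitude, dilated by one voxel to protect partial-volume
  edges) shrinks the unknown count for the second pass.
* **Incremental recon** — one operator per announced spoke fraction,
  computed from the trajectory subset alone (data-agnostic), applied to the
  matching data subset; fraction 1.0 is exactly the plain recon. Each
  checkpoint recomputes its operator because the encode matrix changes with
  the subset.
* **Timing harness** — random complex Gaussian matrices with 1.25× row
  oversampling (comparable to a spiral acquisition's measurement/unknown
  ratio after circular masking). Square Gaussian matrices have
  `σ_min = O(σ_max/N)`, which makes regularized Moore–Penrose residuals
  O(1) and uninformative; the modest oversampling bounds σ_min away from
  zero so the accuracy column is a meaningful machine-independent check.
  Wall-clock values are reported, never asserted.

## Problem sizes

Validation uses scaled-down problems chosen so the full suite runs on a
single CPU core in minutes: the cross-method agreement experiment runs at
64² (8-arm spiral, ≈4096 × 3205 encode), the physics-ladder and SENSE cases
at 32², the structural identities at ≤ 24². The algebra is size-independent;
the 64² experiment already exhibits the 1e-8-level cross-method agreement
that characterizes the method at clinical sizes.

## Known limitations

* CPU only; the blocked Cholesky path is retained as the memory-limited
  strategy rather than a GPU device path.
* Dense matrices only — no gridding/NUFFT, sparse or structured encodings.
* Rigid motion enters row-by-row (a Python loop over k-samples); adequate
  for the small synthetic studies, not tuned for large trajectories.
* The regularization sweep reports plain MSE (matching the zero-image and
  resolution floors it is compared against) alongside NMSE.
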