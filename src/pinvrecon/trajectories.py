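"""k-space trajectories and image grids.

Conventions
-----------
Spatial coordinates ``r`` live in normalized field-of-view (FOV) units: the
pixel with index ``i`` along an axis of size ``N`` sits at ``(i - N/2) / N``,
so the FOV spans ``[-0.5, 0.5)``.  k-space coordinates are in cycles/FOV, so
the product ``k . r`` is dimensionless (turns) and the forward Fourier kernel
is ``exp(+j 2 pi k . r)``.  With integer Cartesian ``k`` in ``[-N/2, N/2)``
this makes the encoding matrix an exact (scaled-orthogonal) DFT matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError

GOLDEN_ANGLE_DEG = 137.508


def _axis_k(n: int) -> np.ndarray:
    """Integer k samples in [-n/2, n/2)."""
    return np.arange(n) - n // 2


def _axis_r(n: int) -> np.ndarray:
    """Pixel-center coordinates (i - n/2)/n in [-0.5, 0.5)."""
    return (np.arange(n) - n / 2.0) / n


@dataclass
class KSpaceTrajectory:
    """Sampling coordinates (cycles/FOV), readout times (s) and interleave labels."""

    coords: np.ndarray            # (N_k, d)
    times: np.ndarray             # (N_k,)
    interleave: np.ndarray        # (N_k,) integer labels
    dim: int

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (N_k, d)")
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.interleave = np.asarray(self.interleave, dtype=np.int32).ravel()
        n_k = self.coords.shape[0]
        if n_k < 1:
            raise ValueError("trajectory must contain at least one sample")
        if self.times.shape != (n_k,) or self.interleave.shape != (n_k,):
            raise ValueError("times/interleave length must match coords")
        if self.dim not in (1, 2, 3) or self.coords.shape[1] != self.dim:
            raise ValueError(f"dim must be 1, 2 or 3 and match coords; got {self.dim}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")
        for lab in np.unique(self.interleave):
            t = self.times[self.interleave == lab]
            if np.any(np.diff(t) < 0):
                raise ValueError("times must be non-decreasing within each interleave")

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    def subset(self, interleaves) -> "KSpaceTrajectory":
        """Restrict to the given interleave labels, preserving acquisition order."""
        interleaves = np.atleast_1d(np.asarray(interleaves))
        if interleaves.size == 0:
            raise ValueError("interleave selection must be non-empty")
        keep = np.isin(self.interleave, interleaves)
        if not np.any(keep):
            raise ValueError("selection matches no interleave label")
        return replace(self, coords=self.coords[keep], times=self.times[keep],
                       interleave=self.interleave[keep])

    def subset_samples(self, selector) -> "KSpaceTrajectory":
        """Restrict to the given k-sample indices / boolean mask."""
        selector = np.asarray(selector)
        coords = self.coords[selector]
        if coords.shape[0] == 0:
            raise ValueError("sample selection is empty")
        return replace(self, coords=coords, times=self.times[selector],
                       interleave=self.interleave[selector])


@dataclass
class ImageGrid:
    """Regular image grid over the normalized FOV with an optional boolean mask.

    ``shape`` is the actual pixel count per axis (already including any
    overdiscretization), so the spacing is ``1/shape[axis]`` per axis; a grid
    overdiscretized by a factor ``o`` relative to a nominal matrix ``N`` has
    ``shape = o*N`` and spacing ``1/(o*N)``.
    """

    shape: tuple
    mask: np.ndarray = None       # boolean over the full grid, row-major
    overdisc: int = 1

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in np.atleast_1d(self.shape))
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape entries must be >= 1, got {self.shape}")
        if int(self.overdisc) < 1:
            raise ValueError("overdisc must be a positive integer")
        self.overdisc = int(self.overdisc)
        n_full = int(np.prod(self.shape))
        if self.mask is None:
            self.mask = np.ones(n_full, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.shape != (n_full,):
                raise ValueError("mask must cover the full grid (row-major)")
        if not np.any(self.mask):
            raise DegenerateInputError("grid mask is empty")

    @property
    def dim(self) -> int:
        return len(self.shape)

    @property
    def n_full(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_voxels(self) -> int:
        """Number of unknowns N_r (masked voxel count)."""
        return int(self.mask.sum())

    def full_coords(self) -> np.ndarray:
        """Coordinates of every grid point, row-major, shape (n_full, d)."""
        axes = [_axis_r(n) for n in self.shape]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    @property
    def coords(self) -> np.ndarray:
        """Coordinates of the masked (active) voxels, shape (N_r, d)."""
        return self.full_coords()[self.mask]

    def extract(self, values: np.ndarray) -> np.ndarray:
        """Restrict a full-grid vector (or stack of them) to the masked voxels."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_full:
            raise ValueError("values must be defined over the full grid")
        return values[..., self.mask]

    def embed(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Embed masked-voxel values back into the full grid (row-major image)."""
        values = np.asarray(values)
        out = np.full(values.shape[:-1] + (self.n_full,), fill,
                      dtype=np.result_type(values.dtype, type(fill)))
        out[..., self.mask] = values
        return out.reshape(values.shape[:-1] + self.shape)


def make_grid(shape, overdisc: int = 1, mask=None) -> ImageGrid:
    """Image grid over the FOV; ``overdisc`` refines the nominal matrix size."""
    shape = tuple(int(s) * int(overdisc) for s in np.atleast_1d(shape))
    return ImageGrid(shape=shape, mask=mask, overdisc=int(overdisc))


def make_cartesian(shape) -> tuple:
    """Fully sampled Cartesian trajectory + matching grid.

    Returns ``(grid, traj)`` with integer k in [-N/2, N/2) per axis (row-major
    ordering, one interleave per leading-axis line); the resulting Fourier
    encode matrix is orthogonal up to a factor sqrt(N_r).
    """
    shape = tuple(int(s) for s in np.atleast_1d(shape))
    if any(s < 1 for s in shape):
        raise ValueError(f"shape entries must be >= 1, got {shape}")
    axes = [_axis_k(n).astype(float) for n in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=-1)
    n_k = coords.shape[0]
    line_len = shape[-1]
    interleave = np.repeat(np.arange(max(n_k // line_len, 1)), line_len)[:n_k]
    traj = KSpaceTrajectory(coords=coords, times=np.zeros(n_k),
                            interleave=interleave, dim=len(shape))
    return ImageGrid(shape=shape), traj


def make_spiral(mtx: int, n_arms: int, pts_per_arm: int,
                rotation: str = "uniform", dwell: float = 4e-6) -> KSpaceTrajectory:
    """Archimedean spiral arms from k=0 to the k-space edge.

    Each arm winds ``mtx/(2*n_arms)`` turns while the radius grows linearly
    from 0 to ``mtx/2`` (Nyquist-spaced arms at the edge for uniform
    rotation).  Arms are rotated by ``2*pi/n_arms`` (uniform) or by the golden
    angle 137.508 deg (golden).  Times rise linearly along each arm from 0
    with the supplied dwell.
    """
    if mtx < 1 or n_arms < 1 or pts_per_arm < 1:
        raise ValueError("mtx, n_arms and pts_per_arm must all be >= 1")
    if rotation not in ("uniform", "golden"):
        raise ValueError(f"rotation must be 'uniform' or 'golden', got {rotation!r}")
    s = np.arange(pts_per_arm) / max(pts_per_arm - 1, 1)
    radius = (mtx / 2.0) * s
    n_turns = mtx / (2.0 * n_arms)
    theta0 = 2 * np.pi * n_turns * s
    if rotation == "uniform":
        offsets = 2 * np.pi * np.arange(n_arms) / n_arms
    else:
        offsets = np.deg2rad(GOLDEN_ANGLE_DEG) * np.arange(n_arms)
    coords = np.empty((n_arms * pts_per_arm, 2))
    for m, off in enumerate(offsets):
        th = theta0 + off
        sl = slice(m * pts_per_arm, (m + 1) * pts_per_arm)
        coords[sl, 0] = radius * np.cos(th)
        coords[sl, 1] = radius * np.sin(th)
    times = np.tile(np.arange(pts_per_arm) * dwell, n_arms)
    interleave = np.repeat(np.arange(n_arms), pts_per_arm)
    return KSpaceTrajectory(coords=coords, times=times, interleave=interleave, dim=2)


def make_radial(mtx: int, n_spokes: int, golden: bool = False,
                dwell: float = 4e-6) -> KSpaceTrajectory:
    """Diametric radial spokes through k=0, ``mtx`` samples per spoke.

    Uniform azimuths span [0, pi) (spokes are diametric); golden-angle
    ordering increments the azimuth by 137.508 deg per spoke.
    """
    if mtx < 1 or n_spokes < 1:
        raise ValueError("mtx and n_spokes must be >= 1")
    radius = _axis_k(mtx).astype(float)  # -mtx/2 .. mtx/2-1, includes 0
    if golden:
        az = np.deg2rad(GOLDEN_ANGLE_DEG) * np.arange(n_spokes)
    else:
        az = np.pi * np.arange(n_spokes) / n_spokes
    coords = np.empty((n_spokes * mtx, 2))
    for m in range(n_spokes):
        sl = slice(m * mtx, (m + 1) * mtx)
        coords[sl, 0] = radius * np.cos(az[m])
        coords[sl, 1] = radius * np.sin(az[m])
    times = np.tile(np.arange(mtx) * dwell, n_spokes)
    interleave = np.repeat(np.arange(n_spokes), mtx)
    return KSpaceTrajectory(coords=coords, times=times, interleave=interleave, dim=2)


def make_random(dim: int, n_points: int, seed: int, mtx: int = 64,
                dwell: float = 4e-6) -> KSpaceTrajectory:
    """Uniform random k-space samples in [-mtx/2, mtx/2)^dim (for benchmarks)."""
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-mtx / 2.0, mtx / 2.0, size=(n_points, dim))
    return KSpaceTrajectory(coords=coords, times=np.arange(n_points) * dwell,
                            interleave=np.zeros(n_points, dtype=np.int32), dim=dim)


def circular_mask(grid: ImageGrid, diameter_fraction: float = 1.0) -> ImageGrid:
    """Mask to a circular (spherical) FOV of the given diameter fraction.

    Keeps voxels with Euclidean radius strictly below ``diameter_fraction/2``
    (in normalized FOV units).  On a square grid with ``diameter_fraction=1``
    this retains ~ pi/4 = 78.5% of the voxels.
    """
    if not 0 < diameter_fraction <= np.sqrt(grid.dim):
        raise ValueError("diameter_fraction must be in (0, sqrt(d)]")
    radius = np.linalg.norm(grid.full_coords(), axis=1)
    mask = grid.mask & (radius < diameter_fraction / 2.0)
    if not np.any(mask):
        raise DegenerateInputError("circular mask removed every voxel")
    return ImageGrid(shape=grid.shape, mask=mask, overdisc=grid.overdisc)
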