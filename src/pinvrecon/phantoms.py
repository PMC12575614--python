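"""Synthetic data: digital phantoms, encoding-factor maps, forward simulation, noise.

Everything here is a pure function of its parameters (and an explicit seed for
the stochastic pieces), so the downstream reconstruction and metrics modules
are fully testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .trajectories import ImageGrid

# Modified (contrast-enhanced) Shepp-Logan ellipse table.
# Columns: additive intensity, semi-axis a (x), semi-axis b (y),
# center x0, center y0, rotation angle phi (degrees), on [-1, 1]^2 coordinates.
_SHEPP_LOGAN_ELLIPSES = np.array([
    [1.00, 0.6900, 0.9200,  0.00,  0.0000,   0.0],
    [-0.80, 0.6624, 0.8740,  0.00, -0.0184,   0.0],
    [-0.20, 0.1100, 0.3100,  0.22,  0.0000, -18.0],
    [-0.20, 0.1600, 0.4100, -0.22,  0.0000,  18.0],
    [0.10, 0.2100, 0.2500,  0.00,  0.3500,   0.0],
    [0.10, 0.0460, 0.0460,  0.00,  0.1000,   0.0],
    [0.10, 0.0460, 0.0460,  0.00, -0.1000,   0.0],
    [0.10, 0.0460, 0.0230, -0.08, -0.6050,   0.0],
    [0.10, 0.0230, 0.0230,  0.00, -0.6060,   0.0],
    [0.10, 0.0230, 0.0460,  0.06, -0.6050,   0.0],
])


@dataclass
class Phantom:
    """Image values over a grid, optionally split into chemical species."""

    values: np.ndarray                      # (N_full,) over the full grid
    grid: ImageGrid
    species: Optional[dict] = None          # name -> (N_full,) vectors

    def masked(self) -> np.ndarray:
        """Values restricted to the grid's active voxels."""
        return self.grid.extract(self.values)

    def image(self) -> np.ndarray:
        return np.asarray(self.values).reshape(self.grid.shape)


@dataclass
class EncodingFactors:
    """Optional encoding factors beyond plain gradient (Fourier) encoding.

    coil_maps      : (n_coils, N_full) complex receive sensitivities on the grid
    b0_map         : (N_full,) off-resonance in rad/s
    species_shifts : (n_species,) chemical shifts in rad/s
    echo_times     : (n_TE,) echo times in seconds
    warp           : callable coords -> warped coords (gradient nonlinearity)
    off_center     : (d,) constant spatial shift in FOV units
    motion         : callable t -> (rotation matrix, translation) rigid motion
    """

    coil_maps: Optional[np.ndarray] = None
    b0_map: Optional[np.ndarray] = None
    species_shifts: Optional[np.ndarray] = None
    echo_times: Optional[np.ndarray] = None
    warp: Optional[Callable] = None
    off_center: Optional[np.ndarray] = None
    motion: Optional[Callable] = None

    @property
    def n_coils(self) -> int:
        return 1 if self.coil_maps is None else int(np.atleast_2d(self.coil_maps).shape[0])

    @property
    def n_echoes(self) -> int:
        return 1 if self.echo_times is None else len(np.atleast_1d(self.echo_times))

    @property
    def n_species(self) -> int:
        return 1 if self.species_shifts is None else len(np.atleast_1d(self.species_shifts))


def shepp_logan_values(coords: np.ndarray) -> np.ndarray:
    """Modified Shepp-Logan intensity at arbitrary 2-D coordinates.

    ``coords`` are in normalized FOV units [-0.5, 0.5); the canonical ellipse
    table lives on [-1, 1]^2, so coordinates are scaled by 2.  Intensities lie
    in [0, 1] (0.2 at the center, 1.0 in the outer rim).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 2:
        raise ValueError("shepp_logan is defined for 2-D grids")
    x = 2.0 * coords[:, 0]
    y = 2.0 * coords[:, 1]
    out = np.zeros(coords.shape[0])
    for amp, a, b, x0, y0, phi in _SHEPP_LOGAN_ELLIPSES:
        c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        out[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    # intensities are sums like 1.0 - 0.8 - 0.2; clip float dust at the ends
    return np.clip(out, 0.0, 1.0)


def shepp_logan(grid: ImageGrid) -> Phantom:
    """Modified (contrast-enhanced) 10-ellipse Shepp-Logan phantom on a 2-D grid."""
    if grid.dim != 2:
        raise ValueError("shepp_logan requires a 2-D grid")
    return Phantom(values=shepp_logan_values(grid.full_coords()), grid=grid)


def coil_map_values(coords: np.ndarray, n_coils: int, width: float = 0.5,
                    phase_slope: float = 2.0) -> np.ndarray:
    """Parametric receive-coil sensitivities at arbitrary coordinates.

    Each coil is a Gaussian magnitude lobe of the given width (FOV units)
    centered on the FOV boundary at equal azimuths, with a linear phase along
    the coil's radial axis; coil m is coil 0 rotated by 2*pi*m/n_coils.
    Unnormalized (see :func:`sim_coil_maps`).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    d = coords.shape[1]
    maps = np.empty((n_coils, coords.shape[0]), dtype=complex)
    for m in range(n_coils):
        az = 2 * np.pi * m / n_coils
        if d == 1:
            center = np.array([0.5 * np.cos(az)])
        else:
            center = np.zeros(d)
            center[0], center[1] = 0.5 * np.cos(az), 0.5 * np.sin(az)
        dist2 = np.sum((coords - center) ** 2, axis=1)
        proj = coords @ center * 2.0  # radial axis of this coil
        maps[m] = np.exp(-dist2 / (2 * width ** 2)) * np.exp(1j * phase_slope * proj)
    return maps


def sim_coil_maps(grid: ImageGrid, n_coils: int, width: float = 0.5,
                  normalize: bool = True) -> np.ndarray:
    """Smooth complex coil maps on the grid, shape (n_coils, n_full).

    With ``normalize=True`` the root-sum-of-squares magnitude is 1 at every
    grid point (as after sum-of-squares normalization of estimated maps).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    maps = coil_map_values(grid.full_coords(), n_coils, width=width)
    if normalize:
        rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        maps = maps / rss
    return maps


def sim_b0_map(grid: ImageGrid, peak_rad_s: float) -> np.ndarray:
    """Smooth low-order-polynomial off-resonance map (rad/s), zero mean on mask.

    A quadratic bowl plus a linear ramp, scaled so the maximum magnitude on
    the masked region equals ``peak_rad_s``.
    """
    r = grid.full_coords()
    poly = np.sum(r ** 2, axis=1) + 0.5 * r[:, 0]
    poly = poly - poly[grid.mask].mean()
    peak = np.max(np.abs(poly[grid.mask]))
    if peak == 0 or peak_rad_s == 0:
        return np.zeros(grid.n_full)
    return peak_rad_s * poly / peak


def sim_warp(amplitude: float) -> Callable:
    """Barrel-distortion spatial warp r -> r * (1 + amplitude * |r|^2).

    amplitude=0 is the identity.  For |amplitude| <= 0.4 the unit FOV maps
    into [-0.6, 0.6)^d.
    """
    def warp(coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        r2 = np.sum(coords ** 2, axis=1, keepdims=True)
        return coords * (1.0 + amplitude * r2)
    return warp


def sim_species(grid: ImageGrid) -> Phantom:
    """Two-species phantom (water/fat) with disjoint elliptical supports."""
    if grid.dim != 2:
        raise ValueError("sim_species requires a 2-D grid")
    r = grid.full_coords()
    x, y = r[:, 0], r[:, 1]
    water = np.where(((x + 0.15) / 0.18) ** 2 + (y / 0.28) ** 2 <= 1.0, 1.0, 0.0)
    fat = np.where(((x - 0.22) / 0.12) ** 2 + (y / 0.20) ** 2 <= 1.0, 0.8, 0.0)
    fat[water > 0] = 0.0  # enforce disjoint supports
    return Phantom(values=water + fat, grid=grid,
                   species={"water": water, "fat": fat})


def forward(encode, image: np.ndarray) -> np.ndarray:
    """Forward-encode an image: data = Encode @ image."""
    matrix = getattr(encode, "matrix", encode)
    image = np.asarray(image)
    if matrix.shape[1] != image.shape[0]:
        raise ValueError(
            f"encode has {matrix.shape[1]} columns but image has length {image.shape[0]}")
    return matrix @ image


def add_noise(data: np.ndarray, level: float, seed: int,
              model: str = "as_printed") -> np.ndarray:
    """Add complex Gaussian noise: data + level * (g1 + 1j*g2/2).

    ``model="as_printed"`` uses an imaginary standard deviation half the real
    one (the literal reading of ``randn(...) + 1i*randn(...)/2``);
    ``model="symmetric"`` uses ``level * (g1 + 1j*g2)/2`` instead.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if model not in ("as_printed", "symmetric"):
        raise ValueError(f"unknown noise model {model!r}")
    data = np.asarray(data)
    if level == 0:
        return data.copy()
    rng = np.random.default_rng(seed)
    g1 = rng.standard_normal(data.shape)
    g2 = rng.standard_normal(data.shape)
    if model == "as_printed":
        noise = level * (g1 + 1j * g2 / 2.0)
    else:
        noise = level * (g1 + 1j * g2) / 2.0
    return data + noise
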