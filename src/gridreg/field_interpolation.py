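"""Upsampling a sparse control-grid displacement field to voxel resolution.

The dense field is a separable basis expansion: for a voxel at position
``(x, y, z)`` the displacement is

    T_up(x, y, z) = sum_{i, j, k} T(i, j, k) * Bx(x; i) * By(y; j) * Bz(z; k)

with the same 1D basis along every axis. Three bases are provided:

* ``trilinear`` — the hat function ``max(0, 1 - |x - xi| / spacing)``;
  interpolating, reproduces constants and linear ramps.
* ``bspline``  — cubic B-spline on a clamped uniform knot vector over the
  normalized axis [0, 1] (Cox–de Boor recursion); approximating but smoother,
  still a partition of unity.
* ``gauss_deconv`` — a truncated Gaussian stencil applied as a transposed
  convolution, with weights renormalized per axis so that constant grids map
  to constant fields (a raw Gaussian does not sum to one on a discrete
  lattice, which would bias every displacement).

Because the expansion is a tensor product, ``upsample`` evaluates it as
three 1D stencil applications (exact, O(N·g) instead of O(N·G));
``upsample_oracle`` is the literal triple sum kept for verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, axis_linear3
from .grid_geometry import (ControlGrid, DenseDisplacementField,
                            GriddedDisplacementField)

__all__ = [
    "BsplineKnots", "UpsamplerConfig", "trilinear_basis", "bspline_basis",
    "gaussian_basis", "make_bspline_knots", "axis_weight_matrix",
    "upsample", "upsample_oracle",
]


@dataclass(frozen=True)
class UpsamplerConfig:
    """Choice of interpolation basis and Gaussian kernel geometry.

    ``gauss_sigma`` is in units of the control-point spacing; the stencil is
    truncated at ``kernel_truncation * gauss_sigma`` spacings. The default
    sigma approximates the cubic B-spline kernel width on a uniform lattice.
    """

    mode: str = "trilinear"
    gauss_sigma: float = 0.45
    kernel_truncation: float = 3.0

    def __post_init__(self):
        if self.mode not in ("trilinear", "bspline", "gauss_deconv"):
            raise ValueError(f"unknown upsampler mode {self.mode!r}")
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.kernel_truncation < 1:
            raise ValueError("kernel_truncation must be >= 1")


@dataclass(frozen=True)
class BsplineKnots:
    """Clamped uniform knot vector on the normalized axis [0, 1]."""

    degree: int
    knots: np.ndarray

    @property
    def num_basis(self) -> int:
        return len(self.knots) - self.degree - 1


def make_bspline_knots(num_control: int, degree: int = 3) -> BsplineKnots:
    """Clamped, linearly sampled knots giving `num_control` basis functions."""
    if not 0 <= degree <= 3:
        raise ValueError("degree must be in 0..3")
    if num_control < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} control points for degree {degree}")
    interior = np.linspace(0.0, 1.0, num_control - degree + 1)[1:-1]
    knots = np.concatenate([np.zeros(degree + 1), interior,
                            np.ones(degree + 1)])
    return BsplineKnots(degree=degree, knots=knots)


# ---------------------------------------------------------------------------
# Scalar basis functions
# ---------------------------------------------------------------------------

def trilinear_basis(x: float, xi: float, spacing: float) -> float:
    """Hat function: 1 at the node, 0 beyond one control spacing."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return max(0.0, 1.0 - abs(x - xi) / spacing)


def bspline_basis(i: int, p: int, x: float, knots: BsplineKnots) -> float:
    """Cox–de Boor recursion with the 0/0 := 0 convention.

    The degree-0 basis is the half-open indicator on [t_i, t_{i+1}); callers
    evaluating at the right axis endpoint take the left limit.
    """
    if not 0.0 <= x < 1.0:
        raise ValueError("x must lie in [0, 1)")
    t = knots.knots

    def B(i, p):
        if p == 0:
            return 1.0 if t[i] <= x < t[i + 1] else 0.0
        left = 0.0
        if t[i + p] > t[i]:
            left = (x - t[i]) / (t[i + p] - t[i]) * B(i, p - 1)
        right = 0.0
        if t[i + p + 1] > t[i + 1]:
            right = (t[i + p + 1] - x) / (t[i + p + 1] - t[i + 1]) * B(i + 1,
                                                                       p - 1)
        return left + right

    return B(i, p)


def gaussian_basis(x: float, xi: float, sigma: float) -> float:
    """Normal kernel (2*pi*sigma^2)^{-1/2} exp(-(x-xi)^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-((x - xi) ** 2) / (2 * sigma ** 2))
                 / np.sqrt(2 * np.pi * sigma ** 2))


# ---------------------------------------------------------------------------
# Axis stencils
# ---------------------------------------------------------------------------

def axis_weight_matrix(n_vox: int, grid_axis: np.ndarray,
                       cfg: UpsamplerConfig) -> np.ndarray:
    """(n_vox, g) basis weights of every control point at every voxel.

    One matrix per axis fully determines the separable expansion; the dense
    field is ``einsum('ai,bj,ck,cijk->cabc', Wx, Wy, Wz, vectors)``.
    """
    g = len(grid_axis)
    xs = np.arange(n_vox, dtype=float)
    if cfg.mode == "trilinear":
        spacing = (n_vox - 1) / (g - 1) if g > 1 else 1.0
        w = np.maximum(0.0, 1.0 - np.abs(xs[:, None] - grid_axis[None, :])
                       / spacing)
    elif cfg.mode == "bspline":
        kn = make_bspline_knots(g, degree=3)
        # normalized axis coordinate; right endpoint as left limit
        u = xs / max(n_vox - 1, 1)
        u = np.minimum(u, 1.0 - 1e-12)
        w = np.empty((n_vox, g))
        for a, ua in enumerate(u):
            for i in range(g):
                w[a, i] = bspline_basis(i, 3, ua, kn)
    else:  # gauss_deconv
        spacing = (n_vox - 1) / (g - 1) if g > 1 else 1.0
        sigma = cfg.gauss_sigma * spacing
        d = np.abs(xs[:, None] - grid_axis[None, :])
        w = np.exp(-d ** 2 / (2 * sigma ** 2)) / np.sqrt(2 * np.pi * sigma ** 2)
        w[d > cfg.kernel_truncation * sigma] = 0.0
        # renormalize so constants are reproduced on the discrete lattice
        w /= w.sum(axis=1, keepdims=True)
    return w


def _weight_matrices(grid: ControlGrid, image_shape, cfg: UpsamplerConfig):
    return [axis_weight_matrix(n, ax, cfg)
            for n, ax in zip(image_shape, grid.axes)]


def upsample(gdf: GriddedDisplacementField, image_shape,
             cfg: UpsamplerConfig | None = None) -> DenseDisplacementField:
    """Upsample a gridded field to a dense per-voxel field (separable)."""
    cfg = cfg or UpsamplerConfig()
    image_shape = tuple(int(n) for n in image_shape)
    if tuple(gdf.grid.image_shape) != image_shape:
        raise ValueError(
            f"grid was built for image {gdf.grid.image_shape}, "
            f"asked to upsample to {image_shape}")
    wx, wy, wz = _weight_matrices(gdf.grid, image_shape, cfg)
    dense = np.einsum("ai,bj,ck,nijk->nabc", wx, wy, wz, gdf.vectors,
                      optimize=True)
    return DenseDisplacementField(vectors=dense)


def upsample_tensor(vectors: Tensor, grid: ControlGrid, image_shape,
                    cfg: UpsamplerConfig | None = None) -> Tensor:
    """Differentiable variant operating on a Tensor of shape (..., gw, gh, gd)."""
    cfg = cfg or UpsamplerConfig()
    wx, wy, wz = _weight_matrices(grid, tuple(image_shape), cfg)
    return axis_linear3(vectors, wx, wy, wz)


def upsample_oracle(gdf: GriddedDisplacementField, image_shape,
                    cfg: UpsamplerConfig | None = None,
                    voxels=None) -> DenseDisplacementField | np.ndarray:
    """Literal triple-sum evaluation of the basis expansion (test reference).

    O(G) per voxel; with ``voxels`` (an iterable of (x, y, z) index triples)
    only those positions are evaluated and an array of displacement vectors
    is returned instead of a full field.
    """
    cfg = cfg or UpsamplerConfig()
    image_shape = tuple(int(n) for n in image_shape)
    gw, gh, gd = gdf.grid.size

    def scalar_weights(n_vox, grid_axis):
        g = len(grid_axis)
        spacing = (n_vox - 1) / (g - 1) if g > 1 else 1.0
        w = np.zeros((n_vox, g))
        if cfg.mode == "trilinear":
            for a in range(n_vox):
                for i in range(g):
                    w[a, i] = trilinear_basis(float(a), grid_axis[i], spacing)
        elif cfg.mode == "bspline":
            kn = make_bspline_knots(g, degree=3)
            for a in range(n_vox):
                u = min(a / max(n_vox - 1, 1), 1.0 - 1e-12)
                for i in range(g):
                    w[a, i] = bspline_basis(i, 3, u, kn)
        else:
            sigma = cfg.gauss_sigma * spacing
            for a in range(n_vox):
                for i in range(g):
                    if abs(a - grid_axis[i]) <= cfg.kernel_truncation * sigma:
                        w[a, i] = gaussian_basis(float(a), grid_axis[i], sigma)
                w[a] /= w[a].sum()
        return w

    wx = scalar_weights(image_shape[0], gdf.grid.axes[0])
    wy = scalar_weights(image_shape[1], gdf.grid.axes[1])
    wz = scalar_weights(image_shape[2], gdf.grid.axes[2])

    def at(x, y, z):
        v = np.zeros(3)
        for i in range(gw):
            for j in range(gh):
                for k in range(gd):
                    b = wx[x, i] * wy[y, j] * wz[z, k]
                    if b != 0.0:
                        v += gdf.vectors[:, i, j, k] * b
        return v

    if voxels is not None:
        return np.array([at(*p) for p in voxels])
    dense = np.zeros((3,) + image_shape)
    for x in range(image_shape[0]):
        for y in range(image_shape[1]):
            for z in range(image_shape[2]):
                dense[:, x, y, z] = at(x, y, z)
    return DenseDisplacementField(vectors=dense)
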