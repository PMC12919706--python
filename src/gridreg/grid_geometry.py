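"""Volumes, control grids, displacement fields, and the warping operator.

Conventions used throughout the package:

* Axes are ordered (x, y, z) matching array axes (W, H, D); coordinates are
  0-based voxel indices of the fixed-image lattice.
* A displacement field stores *gather* displacements in voxel units:
  ``output(x) = moving(x + T(x))`` (the standard spatial-transformer
  backward-warping convention), so the loss compares the warped moving image
  against the fixed image.
* Control grids are corner-aligned: along an axis of length ``n`` with ``g``
  control points, the points sit at ``linspace(0, n-1, g)`` so the extreme
  points coincide with the volume boundary.
* Out-of-bounds samples clamp to the border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from ._tensor import Tensor, warp_trilinear

__all__ = [
    "ImageVolume", "MaskVolume", "ControlGrid", "GriddedDisplacementField",
    "DenseDisplacementField", "LandmarkSet", "GridError",
    "make_control_grid", "warp", "warp_points",
]


class GridError(ValueError):
    """Invalid control-grid specification."""


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    def normalized(self) -> "ImageVolume":
        """Min-max rescale intensities to [0, 1]."""
        lo, hi = float(self.data.min()), float(self.data.max())
        scale = (hi - lo) if hi > lo else 1.0
        return ImageVolume((self.data - lo) / scale, self.spacing, self.origin)


@dataclass
class MaskVolume:
    """Binary segmentation mask sharing the lattice of its paired image."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ControlGrid:
    """Axis-aligned lattice of control points inside a volume.

    ``size`` is the per-axis point count (gw, gh, gd); ``axes`` holds the
    per-axis coordinate vectors and ``coords`` their tensor product, one row
    per control point in C-order (x fastest-varying last).
    """

    size: tuple
    axes: tuple          # (gw,), (gh,), (gd,) coordinate vectors
    image_shape: tuple

    @property
    def num_points(self) -> int:
        gw, gh, gd = self.size
        return gw * gh * gd

    @property
    def coords(self) -> np.ndarray:
        """(G, 3) voxel coordinates of all control points."""
        xs, ys, zs = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)

    @property
    def spacing(self) -> tuple:
        """Control-point spacing per axis, in voxels."""
        return tuple((n - 1) / (g - 1)
                     for n, g in zip(self.image_shape, self.size))

    def normalized_coords(self) -> np.ndarray:
        """Control-point coordinates rescaled to [0, 1] per axis."""
        coords = self.coords.astype(float)
        denom = np.maximum(np.array(self.image_shape, dtype=float) - 1, 1)
        return coords / denom


@dataclass
class GriddedDisplacementField:
    """Displacements at control points: vectors (3, gw, gh, gd), voxel units."""

    grid: ControlGrid
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        expect = (3,) + tuple(self.grid.size)
        if self.vectors.shape != expect:
            raise ValueError(
                f"vectors shape {self.vectors.shape} != {expect}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacements must be finite")


@dataclass
class DenseDisplacementField:
    """Per-voxel gather displacements: vectors (3, W, H, D), voxel units."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError("expected vectors of shape (3, W, H, D)")

    @property
    def spatial_shape(self):
        return self.vectors.shape[1:]


@dataclass
class LandmarkSet:
    """Named voxel-coordinate landmarks."""

    points: np.ndarray            # (K, 3) voxel coordinates
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("expected at least one (x, y, z) point")
        if not self.labels:
            self.labels = [f"p{i}" for i in range(len(self.points))]


def make_control_grid(image_shape, grid_size) -> ControlGrid:
    """Build a corner-aligned, evenly spaced control grid.

    Along each axis the points are ``linspace(0, n-1, g)``; the extreme
    control points therefore lie exactly on the volume boundary.
    """
    image_shape = tuple(int(n) for n in image_shape)
    grid_size = tuple(int(g) for g in grid_size)
    if len(image_shape) != 3 or len(grid_size) != 3:
        raise GridError("image_shape and grid_size must be length 3")
    for n, g in zip(image_shape, grid_size):
        if g < 2:
            raise GridError(f"grid axis must have >= 2 points, got {g}")
        if g > n:
            raise GridError(f"grid axis {g} exceeds image axis {n}")
    axes = tuple(np.linspace(0.0, n - 1.0, g)
                 for n, g in zip(image_shape, grid_size))
    return ControlGrid(size=grid_size, axes=axes, image_shape=image_shape)


def _warp_array(moving: np.ndarray, vectors: np.ndarray, mode: str) -> np.ndarray:
    shape = moving.shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    pos = np.stack(grids) + vectors
    lim = np.array(shape, dtype=float) - 1
    pos = np.clip(pos, 0.0, lim[:, None, None, None])
    if mode == "nearest":
        idx = np.rint(pos).astype(np.intp)
        return moving[idx[0], idx[1], idx[2]]
    out = warp_trilinear(moving.astype(float), Tensor(vectors.astype(float)))
    return out.data


def warp(moving: ImageVolume, ddf: DenseDisplacementField,
         mode: str = "trilinear"):
    """Resample `moving` at displaced coordinates (backward warping).

    ``output(x) = moving(x + T(x))``. Accepts :class:`ImageVolume` or
    :class:`MaskVolume`; the output has the same type and metadata. With
    ``mode='trilinear'`` a Tensor-valued displacement stays differentiable
    via :func:`gridreg._tensor.warp_trilinear`.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown warp mode {mode!r}")
    data = moving.data
    if data.shape != ddf.spatial_shape:
        raise ValueError(
            f"image shape {data.shape} != field shape {ddf.spatial_shape}")
    warped = _warp_array(np.asarray(data, dtype=float), ddf.vectors, mode)
    if isinstance(moving, MaskVolume):
        if mode == "nearest":
            warped = warped.astype(moving.data.dtype)
        return MaskVolume(np.rint(warped).astype(np.uint8) if mode == "nearest"
                          else _binarize_safe(warped),
                          moving.spacing, moving.origin)
    return ImageVolume(warped, moving.spacing, moving.origin)


def _binarize_safe(soft: np.ndarray) -> np.ndarray:
    return (soft >= 0.5).astype(np.uint8)


def warp_soft_mask(mask: MaskVolume, ddf) -> np.ndarray:
    """Trilinear-warp a binary mask keeping the soft [0, 1] values.

    Used by the differentiable Dice loss; `ddf` may be a Tensor field.
    Returns the warped soft occupancy (Tensor if ddf is a Tensor).
    """
    vec = ddf if isinstance(ddf, Tensor) else Tensor(np.asarray(ddf.vectors,
                                                                dtype=float))
    return warp_trilinear(mask.data.astype(float), vec)


def _sample_field(vectors: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear sample of a (3, W, H, D) field at continuous points (K, 3)."""
    shape = vectors.shape[1:]
    lim = np.array(shape) - 1
    p = np.clip(pts, 0.0, lim)
    f = np.minimum(np.floor(p), np.maximum(lim - 1, 0)).astype(np.intp)
    t = p - f
    out = np.zeros_like(p)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                ix = np.clip(f[:, 0] + dx, 0, shape[0] - 1)
                iy = np.clip(f[:, 1] + dy, 0, shape[1] - 1)
                iz = np.clip(f[:, 2] + dz, 0, shape[2] - 1)
                out += w[:, None] * vectors[:, ix, iy, iz].T
    return out


def warp_points(points: LandmarkSet, ddf: DenseDisplacementField,
                n_iter: int = 5) -> LandmarkSet:
    """Map landmarks consistently with the image-warping convention.

    Image warping gathers: a feature at moving-image position ``p`` appears
    in the warped image at the position ``q`` solving ``q + T(q) = p``. The
    fixed point is found by iterating ``q <- p - T(q)`` starting from
    ``q = p`` (exact for constant fields; converges for smooth fields with
    displacement gradients below 1). Points leaving the volume are excluded
    with a warning.
    """
    shape = np.array(ddf.spatial_shape, dtype=float)
    pts = np.asarray(points.points, dtype=float)
    q = pts.copy()
    for _ in range(n_iter):
        q = pts - _sample_field(ddf.vectors, q)
    ok = np.all((q >= 0) & (q <= shape - 1), axis=1)
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} landmark(s) mapped out of bounds; "
                      "excluded", stacklevel=2)
    labels = [l for l, keep in zip(points.labels, ok) if keep]
    return LandmarkSet(points=q[ok], labels=labels)
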