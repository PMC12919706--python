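"""Seeded synthetic registration pairs with known ground-truth deformation.

The phantom emulates the image structure the sparse-grid model assumes: a
central quasi-ellipsoidal "organ" with a homogeneous interior and contrasted
boundary, a handful of smooth intensity blobs acting as distinctive
features, and additive Gaussian intensity noise. The moving image is the
phantom; the fixed image is the phantom warped by a smooth random
displacement drawn on a coarse control grid (so every pair is solvable by
construction), plus fresh noise. Masks and landmarks are transported with
the same field and convention as the images.

All randomness flows through ``numpy.random.default_rng`` (PCG64) from the
single seed in :class:`PhantomSpec`, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid_geometry import (ImageVolume, LandmarkSet, MaskVolume,
                            GriddedDisplacementField, make_control_grid,
                            warp, warp_points)
from .field_interpolation import UpsamplerConfig, upsample

__all__ = ["PhantomSpec", "RegistrationPair", "generate_phantom",
           "generate_true_deformation", "make_pair"]


@dataclass
class PhantomSpec:
    """Generator parameters.

    ``max_disp`` (voxels) must stay below half the true control spacing so
    the ground-truth deformation cannot fold; ``deform_grid`` is the grid
    the truth lives on (coarser than or equal to any model grid, keeping
    recovery well-posed).
    """

    shape: tuple = (32, 32, 32)
    num_blobs: int = 6
    organ_radius: float = 0.30
    noise_sd: float = 0.02
    deform_grid: tuple = (5, 5, 5)
    max_disp: float = 2.5
    num_landmarks: int = 5
    spacing: tuple = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        half_spacing = min((n - 1) / (g - 1)
                           for n, g in zip(self.shape, self.deform_grid)) / 2
        if self.max_disp >= half_spacing:
            raise ValueError(
                f"max_disp {self.max_disp} must be < half the control "
                f"spacing ({half_spacing:.2f}) to guarantee invertibility")


@dataclass
class RegistrationPair:
    """One synthetic case: images, masks, landmarks, and the true field."""

    fixed: ImageVolume
    moving: ImageVolume
    fixed_mask: MaskVolume
    moving_mask: MaskVolume
    fixed_landmarks: LandmarkSet
    moving_landmarks: LandmarkSet
    truth: GriddedDisplacementField


def _organ_mask(spec: PhantomSpec, rng) -> np.ndarray:
    shape = np.array(spec.shape, dtype=float)
    center = shape / 2 + rng.uniform(-1.5, 1.5, size=3)
    radii = spec.organ_radius * shape * rng.uniform(0.85, 1.15, size=3)
    grids = np.indices(spec.shape).astype(float)
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return (r2 <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec):
    """Return (ImageVolume, MaskVolume, LandmarkSet), seed-determined.

    Intensity = dim background + bright organ plateau + smooth blobs, noise
    added, min-max normalized to [0, 1]. Landmarks sit on blob centers (the
    distinct intensity features), preferring those inside the volume core.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    mask = _organ_mask(spec, rng)
    img = 0.15 + 0.55 * mask.astype(float)

    margin = 0.18
    lo = np.array(shape) * margin
    hi = np.array(shape) * (1 - margin)
    centers = rng.uniform(lo, hi, size=(spec.num_blobs, 3))
    sigmas = rng.uniform(1.2, 2.5, size=spec.num_blobs)
    amps = rng.uniform(0.25, 0.45, size=spec.num_blobs)
    grids = np.indices(shape).astype(float)
    for c, s, a in zip(centers, sigmas, amps):
        r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        img += a * np.exp(-r2 / (2 * s ** 2))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    img -= img.min()
    img /= img.max()

    k = min(spec.num_landmarks, spec.num_blobs)
    landmarks = LandmarkSet(points=centers[:k],
                            labels=[f"blob{i}" for i in range(k)])
    return (ImageVolume(img, spec.spacing), MaskVolume(mask, spec.spacing),
            landmarks)


def generate_true_deformation(spec: PhantomSpec) -> GriddedDisplacementField:
    """Smooth random control-grid displacements, clipped to ``max_disp``.

    White noise per control point is smoothed along the grid axes and
    rescaled so the largest component magnitude equals ``max_disp``; under
    the ``max_disp`` < spacing/2 precondition the upsampled field is
    fold-free.
    """
    rng = np.random.default_rng(spec.seed + 10_000)
    grid = make_control_grid(spec.shape, spec.deform_grid)
    raw = rng.standard_normal((3,) + tuple(spec.deform_grid))
    smooth = gaussian_filter(raw, sigma=(0, 0.8, 0.8, 0.8), mode="nearest")
    peak = np.abs(smooth).max()
    if spec.max_disp == 0 or peak == 0:
        vec = np.zeros_like(smooth)
    else:
        vec = smooth * (spec.max_disp / peak)
    vec = np.clip(vec, -spec.max_disp, spec.max_disp)
    return GriddedDisplacementField(grid=grid, vectors=vec)


def make_pair(spec: PhantomSpec,
              upsampler: UpsamplerConfig | None = None) -> RegistrationPair:
    """Build a full fixed/moving case with consistent labels.

    ``fixed = warp(moving, upsample(truth)) + fresh noise``; the fixed mask
    is the moving mask warped with nearest-neighbor sampling, and the fixed
    landmarks are the moving landmarks pushed through the same field.
    """
    upsampler = upsampler or UpsamplerConfig()
    moving, moving_mask, moving_lm = generate_phantom(spec)
    truth = generate_true_deformation(spec)
    ddf = upsample(truth, spec.shape, upsampler)

    fixed_img = warp(moving, ddf, mode="trilinear")
    rng = np.random.default_rng(spec.seed + 20_000)
    data = fixed_img.data.copy()
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    data = np.clip(data, 0.0, 1.0)
    fixed = ImageVolume(data, spec.spacing)
    fixed_mask = warp(moving_mask, ddf, mode="nearest")
    fixed_lm = warp_points(moving_lm, ddf)
    return RegistrationPair(fixed=fixed, moving=moving,
                            fixed_mask=fixed_mask, moving_mask=moving_mask,
                            fixed_landmarks=fixed_lm,
                            moving_landmarks=moving_lm, truth=truth)
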