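"""Training objectives: uncertainty-weighted similarity, Dice, bending energy.

All spatial sums are normalized to means over the voxel domain so that the
loss weights are comparable across image sizes; the default bending weight
is the literature's raw-sum value rescaled by a typical clinical voxel count
(see the methods note). Every loss accepts either plain numpy arrays (for
evaluation) or autodiff Tensors (for training), returning the same type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor
from .grid_geometry import ImageVolume, MaskVolume

__all__ = ["LossWeights", "LossReport", "similarity_image",
           "uncertainty_loss", "dice_loss", "bending_energy", "total_loss"]

_VAR_FLOOR = 1e-6     # lower clamp on interpolated variance


@dataclass
class LossWeights:
    """Weights of the composite objective.

    lambda0 — weight of the log-variance penalty inside the uncertainty loss;
    lambda1/2/3 — weights of the uncertainty, Dice, and bending terms;
    dice_eps — Dice smoothing constant; mc_samples — Monte Carlo draws per step.
    """

    lambda0: float = 0.5
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.01
    dice_eps: float = 1e-5
    mc_samples: int = 4

    def __post_init__(self):
        if min(self.lambda0, self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.dice_eps <= 0:
            raise ValueError("dice_eps must be positive")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")


@dataclass
class LossReport:
    """Itemized loss values; total = l1*u + l2*d + l3*b."""

    total: float
    uncertainty_term: float
    dice_term: float
    bending_term: float


def _data(x):
    if isinstance(x, (ImageVolume, MaskVolume)):
        return x.data
    return x


def similarity_image(warped, fixed):
    """Mean squared intensity error over the voxel domain."""
    w, f = _data(warped), _data(fixed)
    wshape = w.shape if not isinstance(w, Tensor) else w.shape
    fshape = f.shape if not isinstance(f, Tensor) else f.shape
    if tuple(wshape) != tuple(fshape):
        raise ValueError(f"shape mismatch {wshape} vs {fshape}")
    if isinstance(w, Tensor) or isinstance(f, Tensor):
        d = as_tensor(w) - as_tensor(f)
        return (d * d).mean()
    return float(np.mean((np.asarray(w, dtype=float) - np.asarray(f, dtype=float)) ** 2))


def uncertainty_loss(moving, fixed, samples, var_grid, upsampler,
                     weights: LossWeights, seed=None):
    """Heteroscedastic similarity: Monte Carlo residuals over 2*sigma^2 plus
    a log-variance penalty.

    ``samples`` are displacement fields drawn on the control grid by the
    reparameterization trick; each is upsampled and used to warp ``moving``.
    ``var_grid`` is the per-control-point variance (3, gw, gh, gd) on the
    same grid as the samples; it is upsampled with the same basis as the
    displacement, averaged over the three vector components to a scalar
    per-voxel uncertainty, and clamped below at 1e-6. With ``sigma^2 == 1``
    and ``lambda0 == 0`` the loss reduces to half the mean squared residual.
    The ``seed`` argument is accepted for API symmetry; sampling happens
    upstream.
    """
    from .field_interpolation import upsample_tensor

    S = len(samples)
    if S < 1:
        raise ValueError("need at least one Monte Carlo sample")
    mov = np.asarray(_data(moving), dtype=float)
    fix = np.asarray(_data(fixed), dtype=float)

    first = samples[0]
    grid = first.grid if hasattr(first, "grid") else None
    if grid is None:
        raise ValueError("samples must be GriddedDisplacementField-like")
    var = var_grid if isinstance(var_grid, Tensor) else Tensor(
        np.asarray(var_grid, dtype=float))
    if np.any(var.data <= 0):
        raise ValueError("variances must be strictly positive")
    var_dense = upsample_tensor(var, grid, mov.shape, upsampler)
    var_vox = var_dense.mean(axis=0).clip_min(_VAR_FLOOR)

    from ._tensor import warp_trilinear

    res_term = None
    for s in samples:
        vec = s.vectors if isinstance(s.vectors, Tensor) else Tensor(
            np.asarray(s.vectors, dtype=float))
        dense = upsample_tensor(vec, grid, mov.shape, upsampler)
        warped = warp_trilinear(mov, dense)
        r = warped - Tensor(fix)
        term = (r * r / (2.0 * var_vox)).mean()
        res_term = term if res_term is None else res_term + term
    loss = res_term * (1.0 / S)
    if weights.lambda0 > 0:
        loss = loss + weights.lambda0 * var_vox.log().mean()
    return loss


def dice_loss(fixed_mask, warped_mask, eps: float = 1e-5):
    """Soft Dice loss 1 - 2|A.B| / (|A| + |B| + eps); 0 for identical masks."""
    a, b = _data(fixed_mask), _data(warped_mask)
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError("mask shapes differ")
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a, b = as_tensor(a), as_tensor(b)
        inter = (a * b).sum()
        return 1.0 - (2.0 * inter) / (a.sum() + b.sum() + eps)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(1.0 - 2.0 * (a * b).sum() / (a.sum() + b.sum() + eps))


def bending_energy(ddf):
    """Mean squared second derivative of the displacement field.

    Central finite differences on the unit voxel lattice, interior voxels
    only; the sum over the three pure second derivatives plus twice the
    three mixed derivatives, per vector component, is divided by the total
    voxel count. Zero on any affine field.
    """
    vec = ddf if isinstance(ddf, Tensor) else None
    if vec is None:
        arr = ddf.vectors if hasattr(ddf, "vectors") else np.asarray(ddf)
        vec = Tensor(np.asarray(arr, dtype=float))
        want_float = True
    else:
        want_float = False
    if vec.ndim != 4 or vec.shape[0] != 3:
        raise ValueError("expected a (3, W, H, D) field")
    if min(vec.shape[1:]) < 3:
        raise ValueError("each axis needs >= 3 voxels for second differences")

    N = int(np.prod(vec.shape[1:]))
    c = vec[:, 1:-1, 1:-1, 1:-1]
    dxx = vec[:, 2:, 1:-1, 1:-1] - 2.0 * c + vec[:, :-2, 1:-1, 1:-1]
    dyy = vec[:, 1:-1, 2:, 1:-1] - 2.0 * c + vec[:, 1:-1, :-2, 1:-1]
    dzz = vec[:, 1:-1, 1:-1, 2:] - 2.0 * c + vec[:, 1:-1, 1:-1, :-2]
    dxy = (vec[:, 2:, 2:, 1:-1] - vec[:, 2:, :-2, 1:-1]
           - vec[:, :-2, 2:, 1:-1] + vec[:, :-2, :-2, 1:-1]) * 0.25
    dxz = (vec[:, 2:, 1:-1, 2:] - vec[:, 2:, 1:-1, :-2]
           - vec[:, :-2, 1:-1, 2:] + vec[:, :-2, 1:-1, :-2]) * 0.25
    dyz = (vec[:, 1:-1, 2:, 2:] - vec[:, 1:-1, 2:, :-2]
           - vec[:, 1:-1, :-2, 2:] + vec[:, 1:-1, :-2, :-2]) * 0.25
    total = ((dxx * dxx + dyy * dyy + dzz * dzz).sum()
             + 2.0 * (dxy * dxy + dxz * dxz + dyz * dyz).sum())
    out = total * (1.0 / N)
    return out.item() if want_float else out


def total_loss(components: dict, weights: LossWeights,
               masks_available: bool = True):
    """Weighted sum of the loss terms; Dice enters only when masks exist.

    ``components`` maps 'uncertainty'/'dice'/'bending' to scalars (floats or
    Tensors). Returns ``(total, LossReport)`` where total keeps the input
    type so it can be backpropagated.
    """
    u = components.get("uncertainty", 0.0)
    d = components.get("dice", 0.0) if masks_available else 0.0
    b = components.get("bending", 0.0)
    total = weights.lambda1 * u
    if masks_available and weights.lambda2 > 0:
        total = total + weights.lambda2 * d
    if weights.lambda3 > 0:
        total = total + weights.lambda3 * b

    def val(x):
        return x.item() if isinstance(x, Tensor) else float(x)

    report = LossReport(total=val(total), uncertainty_term=val(u),
                        dice_term=val(d) if masks_available else 0.0,
                        bending_term=val(b))
    return total, report
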