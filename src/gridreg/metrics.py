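"""Registration accuracy and deformation-regularity metrics.

Accuracy: Dice overlap between fixed and warped masks, and centroid distance
(mean Euclidean distance in mm between corresponding landmark points or mask
centroids). Regularity: statistics of the Jacobian determinant of the mapping
phi(x) = x + T(x) — voxels with det J < 0 are folded (locally non-invertible),
and |log det J| summarizes local volume change (0 for an incompressible map).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_geometry import DenseDisplacementField, LandmarkSet, MaskVolume

__all__ = ["JacobianStats", "dice_coefficient", "centroid_distance",
           "jacobian_stats"]


@dataclass
class JacobianStats:
    """Summary of per-voxel Jacobian determinants of phi = id + T.

    ``logdet_mean``/``logdet_sd`` are the mean and SD of |log det J| over
    voxels with positive determinant (the magnitude convention is recorded
    here so downstream reports are unambiguous); ``folding_rate`` is the
    percentage of voxels with negative determinant.
    """

    logdet_mean: float
    logdet_sd: float
    folding_rate: float
    det_map: np.ndarray
    convention: str = "mean |log det J| over det>0 voxels"


def dice_coefficient(a, b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); both masks empty counts as 1."""
    da = (a.data if isinstance(a, MaskVolume) else np.asarray(a)) > 0.5
    db = (b.data if isinstance(b, MaskVolume) else np.asarray(b)) > 0.5
    if da.shape != db.shape:
        raise ValueError("mask shapes differ")
    sa, sb = int(da.sum()), int(db.sum())
    if sa == 0 and sb == 0:
        return 1.0
    return float(2.0 * np.logical_and(da, db).sum() / (sa + sb))


def _centroid(mask: MaskVolume) -> np.ndarray:
    m = np.asarray(mask.data, dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("cannot take the centroid of an empty mask")
    idx = np.indices(m.shape, dtype=float)
    return np.array([float((g * m).sum() / total) for g in idx])


def centroid_distance(fixed, warped, spacing=None) -> float:
    """Mean Euclidean distance (mm) between corresponding centroids.

    For :class:`LandmarkSet` pairs the distance is averaged over the K
    corresponding points; for :class:`MaskVolume` pairs it is the distance
    between the two mask centroids. Voxel differences are scaled by the
    per-axis spacing before taking the norm.
    """
    if isinstance(fixed, LandmarkSet) and isinstance(warped, LandmarkSet):
        if len(fixed.points) != len(warped.points):
            raise ValueError("landmark sets must correspond pairwise")
        sp = np.asarray(spacing if spacing is not None else (1.0, 1.0, 1.0),
                        dtype=float)
        diff = (fixed.points - warped.points) * sp
        return float(np.mean(np.linalg.norm(diff, axis=1)))
    if isinstance(fixed, MaskVolume) and isinstance(warped, MaskVolume):
        sp = np.asarray(spacing if spacing is not None else fixed.spacing,
                        dtype=float)
        diff = (_centroid(fixed) - _centroid(warped)) * sp
        return float(np.linalg.norm(diff))
    raise TypeError("expected two LandmarkSets or two MaskVolumes")


def jacobian_stats(ddf: DenseDisplacementField, spacing=None) -> JacobianStats:
    """Per-voxel determinant of J = I + grad T and its summaries.

    Spatial derivatives use central differences in the interior and
    one-sided differences at the borders (numpy.gradient), on the voxel
    lattice. ``spacing`` is accepted for interface symmetry; displacements
    and derivatives are lattice-native, so the determinant is dimensionless
    either way.
    """
    vec = np.asarray(ddf.vectors, dtype=float)
    if min(vec.shape[1:]) < 2:
        raise ValueError("each axis needs >= 2 voxels for gradients")
    # J[a, b] = d phi_a / d x_b = delta_ab + d T_a / d x_b
    J = np.empty(vec.shape[1:] + (3, 3))
    for a in range(3):
        grads = np.gradient(vec[a], axis=(0, 1, 2))
        for b in range(3):
            J[..., a, b] = grads[b]
        J[..., a, a] += 1.0
    det = np.linalg.det(J)
    n = det.size
    folding = 100.0 * float((det < 0).sum()) / n
    pos = det > 0
    if pos.any():
        mag = np.abs(np.log(det[pos]))
        logdet_mean, logdet_sd = float(mag.mean()), float(mag.std())
    else:
        logdet_mean = logdet_sd = float("nan")
    return JacobianStats(logdet_mean=logdet_mean, logdet_sd=logdet_sd,
                         folding_rate=folding, det_map=det)
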