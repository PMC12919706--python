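"""NIfTI and landmark-CSV input/output.

Volumes are stored with a diagonal affine built from voxel spacing and world
origin; reading preserves whatever affine is present and recovers spacing
from the affine column norms. Displacement fields are stored as 4D NIfTI
with the vector component on the last axis. Landmark files are CSV with the
header ``label,x,y,z`` in voxel coordinates.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid_geometry import (DenseDisplacementField, ImageVolume, LandmarkSet,
                            MaskVolume)

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "read_ddf", "write_ddf", "read_landmarks", "write_landmarks"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _spacing_origin(img) -> tuple:
    aff = img.affine
    spacing = tuple(float(s) for s in np.linalg.norm(aff[:3, :3], axis=0))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return ImageVolume(np.asarray(img.get_fdata(), dtype=float),
                       spacing, origin)


def write_volume(path, vol: ImageVolume) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                             _affine(vol.spacing, vol.origin)), str(path))


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return MaskVolume((np.asarray(img.get_fdata()) > 0.5).astype(np.uint8),
                      spacing, origin)


def write_mask(path, mask: MaskVolume) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8),
                             _affine(mask.spacing, mask.origin)), str(path))


def write_ddf(path, field, spacing=(1.0, 1.0, 1.0),
              origin=(0.0, 0.0, 0.0)) -> None:
    """Store a (3, W, H, D) displacement array as (W, H, D, 3) NIfTI."""
    vec = field.vectors if hasattr(field, "vectors") else np.asarray(field)
    nib.save(nib.Nifti1Image(np.moveaxis(vec, 0, -1).astype(np.float32),
                             _affine(spacing, origin)), str(path))


def read_ddf(path) -> DenseDisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("expected a (W, H, D, 3) displacement NIfTI")
    return DenseDisplacementField(vectors=np.moveaxis(data, -1, 0))


def write_landmarks(path, landmarks: LandmarkSet) -> None:
    df = pd.DataFrame({"label": landmarks.labels,
                       "x": landmarks.points[:, 0],
                       "y": landmarks.points[:, 1],
                       "z": landmarks.points[:, 2]})
    df.to_csv(path, index=False)


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    return LandmarkSet(points=df[["x", "y", "z"]].to_numpy(dtype=float),
                       labels=[str(l) for l in df["label"]])


def write_pair_dir(case_dir, pair) -> None:
    """Write one synthetic case to a directory (NIfTI + CSV)."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    write_volume(case_dir / "fixed.nii.gz", pair.fixed)
    write_volume(case_dir / "moving.nii.gz", pair.moving)
    write_mask(case_dir / "fixed_mask.nii.gz", pair.fixed_mask)
    write_mask(case_dir / "moving_mask.nii.gz", pair.moving_mask)
    write_landmarks(case_dir / "fixed_landmarks.csv", pair.fixed_landmarks)
    write_landmarks(case_dir / "moving_landmarks.csv", pair.moving_landmarks)
    write_ddf(case_dir / "truth_gdf.nii.gz", pair.truth,
              spacing=pair.fixed.spacing)
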