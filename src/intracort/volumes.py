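"""Voxelwise T1w/T2w ratio volumes.

The ratio R = T1w/T2w of co-registered, bias-corrected T1- and T2-weighted
intensities is a voxelwise proxy for relative myelin content: T1w intensity
rises and T2w intensity falls with myelin, so the ratio amplifies the myelin
signal while cancelling multiplicative nuisance fields shared by the two
acquisitions.  This module computes R and restricts it to gray matter.

Volumes use a *corner* voxel-coordinate convention internally: the affine maps
continuous voxel coordinates to world mm, and voxel ``(i, j, k)`` occupies the
half-open cube ``[i, i+1) x [j, j+1) x [k, k+1)`` in voxel coordinates, with
its center at ``(i+.5, j+.5, k+.5)``.  NIfTI I/O converts to and from the
standard center-based NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "LabelVolume",
    "compute_ratio_volume",
    "mask_to_gm",
    "GM",
    "WM",
    "BACKGROUND",
]

BACKGROUND = 0
GM = 1
WM = 2

_HALF_VOXEL = np.array([0.5, 0.5, 0.5, 1.0])


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def _corner_to_nifti_affine(affine: np.ndarray) -> np.ndarray:
    """Shift a corner-convention affine to NIfTI's voxel-center convention."""
    out = affine.copy()
    out[:3, 3] = (affine @ _HALF_VOXEL)[:3]
    return out


def _nifti_to_corner_affine(affine: np.ndarray) -> np.ndarray:
    out = affine.copy()
    out[:3, 3] = out[:3, 3] - affine[:3, :3] @ np.array([0.5, 0.5, 0.5])
    return out


@dataclass
class ScalarVolume:
    """A 3-D scalar grid with a voxel-to-world affine and a validity mask."""

    values: np.ndarray
    affine: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.affine = _check_affine(self.affine)
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("values and valid masks have different shapes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (n, 3) to continuous corner voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, coords: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        return pts @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        data = np.where(self.valid, self.values, np.nan)
        return nib.Nifti1Image(data.astype(np.float64), _corner_to_nifti_affine(self.affine))

    @classmethod
    def from_nifti(cls, img_or_path) -> "ScalarVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        data = np.asarray(img.get_fdata(), dtype=float)
        valid = np.isfinite(data)
        data = np.where(valid, data, 0.0)
        return cls(data, _nifti_to_corner_affine(np.asarray(img.affine, dtype=float)), valid)


@dataclass
class LabelVolume:
    """Integer tissue labels (0 background, 1 GM, 2 WM) on a scalar grid."""

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = np.rint(self.labels).astype(np.int32)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int16), _corner_to_nifti_affine(self.affine))

    @classmethod
    def from_nifti(cls, img_or_path) -> "LabelVolume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        data = np.rint(np.asarray(img.get_fdata())).astype(np.int32)
        return cls(data, _nifti_to_corner_affine(np.asarray(img.affine, dtype=float)))


def _require_same_grid(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: grid shapes differ ({a.shape} vs {b.shape})")
    if not np.allclose(a.affine, b.affine, atol=1e-9):
        raise ValueError(f"{what}: affines differ")


def compute_ratio_volume(
    t1: ScalarVolume, t2: ScalarVolume, epsilon: float | None = None
) -> ScalarVolume:
    """Voxelwise ratio R = T1/T2 with a guard against vanishing T2.

    Parameters
    ----------
    t1, t2
        Co-registered intensity volumes on the same grid.  Intensities must be
        non-negative (bias correction and registration happen upstream).
    epsilon
        Intensity floor below which a T2 voxel is considered unusable; such
        voxels are marked invalid rather than assigned a number.  Defaults to
        ``1e-6`` times the 99th percentile of valid T2 intensities, a relative
        floor that is unit independent.
    """
    _require_same_grid(t1, t2, "compute_ratio_volume")
    if np.any(t1.values[t1.valid] < 0) or np.any(t2.values[t2.valid] < 0):
        raise ValueError("negative intensities are not allowed")
    if epsilon is None:
        ref = t2.values[t2.valid]
        epsilon = 1e-6 * (np.percentile(ref, 99) if ref.size else 1.0)
    valid = t1.valid & t2.valid & (t2.values > epsilon)
    values = np.zeros_like(t1.values)
    np.divide(t1.values, t2.values, out=values, where=valid)
    return ScalarVolume(values, t1.affine, valid)


def mask_to_gm(r: ScalarVolume, labels: LabelVolume) -> ScalarVolume:
    """Restrict a ratio volume to gray-matter voxels.

    Returns a volume valid only where the label is GM *and* the input was
    valid.  A volume with no valid voxel is returned as such (degenerate
    masks are the caller's concern; ``out.valid.sum()`` exposes the count).
    """
    _require_same_grid(r, labels, "mask_to_gm")
    valid = r.valid & (labels.labels == GM)
    return ScalarVolume(r.values, r.affine, valid)
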