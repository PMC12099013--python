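"""Binary volumes in a fixed RAS frame, plus NIfTI round-trip.

Every volume in this package lives on an axis-aligned RAS grid: axis 0 runs
left→right (sagittal index), axis 1 posterior→anterior, axis 2
inferior→superior.  The world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` in millimetres.  Inputs in other
orientations are reorientated on read; oblique affines are not supported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ValidationError

log = logging.getLogger(__name__)

__all__ = ["BinaryVolume", "read_volume", "write_volume"]


@dataclass
class BinaryVolume:
    """A 3D binary mask with millimetre geometry.

    Parameters
    ----------
    voxels
        3D boolean array, ``(sagittal, coronal, axial)`` = ``(X, Y, Z)``
        in RAS.
    spacing
        Voxel edge lengths in mm, one per axis, strictly positive.
    origin
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    orientation
        Axis-label tag; always ``"RAS"`` after construction/reading.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError("voxels must be a 3D array")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels > 0.5
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape == ():
            self.spacing = np.repeat(float(self.spacing), 3)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError("spacing must be 3 strictly positive mm values")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValidationError("origin must be a 3-vector (mm)")
        if self.orientation != "RAS":
            raise ValidationError("volumes must be in RAS orientation")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4×4 voxel→world affine (axis aligned)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def world_coords(self) -> np.ndarray:
        """(n, 3) world coordinates (mm) of all foreground voxels."""
        idx = np.argwhere(self.voxels)
        return self.origin + idx * self.spacing

    def translated(self, shift_voxels: tuple[int, int, int]) -> "BinaryVolume":
        """Shift the mask by whole voxels inside the same grid (zero fill)."""
        out = np.zeros_like(self.voxels)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, s in enumerate(shift_voxels):
            n = self.voxels.shape[ax]
            if abs(s) >= n:
                raise ValidationError("shift exceeds volume extent")
            if s >= 0:
                dst[ax], src[ax] = slice(s, n), slice(0, n - s)
            else:
                dst[ax], src[ax] = slice(0, n + s), slice(-s, n)
        out[tuple(dst)] = self.voxels[tuple(src)]
        return BinaryVolume(out, self.spacing.copy(), self.origin.copy())


def read_volume(path: str | Path) -> BinaryVolume:
    """Read a NIfTI mask, reorienting to RAS.

    Non-binary data are thresholded at 0.5 with a warning.  The original
    orientation is logged so provenance is never silent.
    """
    img = nib.load(str(path))
    orig_ax = "".join(nib.aff2axcodes(img.affine))
    img = nib.as_closest_canonical(img)
    if orig_ax != "RAS":
        log.info("reoriented %s from %s to RAS", path, orig_ax)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        warnings.warn(
            f"{path}: non-binary data thresholded at 0.5", stacklevel=2
        )
    aff = img.affine
    spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    off_diag = np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))).max()
    if off_diag > 1e-3 * spacing.min():
        warnings.warn(
            f"{path}: oblique affine; treating grid as axis-aligned",
            stacklevel=2,
        )
    return BinaryVolume(data > 0.5, spacing=spacing, origin=aff[:3, 3])


def write_volume(vol: BinaryVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (uint8 data, RAS affine)."""
    img = nib.Nifti1Image(vol.voxels.astype(np.uint8), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))
    return Path(path)
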