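"""Corpus-callosum segmentation from a white-matter mask.

The CC is recovered by template-mask propagation: the subject WM volume is
aligned to a template space with a moments-based affine (centroid
translation, principal-axes rotation, per-axis scale from second moments),
the template CC mask is propagated back through the inverse affine, dilated
by a metric margin, intersected with the subject WM, and reduced to its
largest connected component.  A generous dilation margin absorbs the
residual misalignment that a non-rigid registration would otherwise remove;
the intersection with the WM mask is what actually defines the output
boundary, so the final segmentation is insensitive to moderate alignment
error as long as the dilated mask covers the CC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import SegmentationError, ValidationError
from .synthetic import CCShapeSpec, generate_cc_mask
from .volume import BinaryVolume

__all__ = [
    "AffineTransform",
    "TemplateAtlas",
    "affine_align",
    "segment_cc",
    "extract_midsagittal_slices",
    "default_template",
]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity


@dataclass
class AffineTransform:
    """World-space affine ``x_template = linear @ x_subject + translation`` (mm)."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.linear.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("affine needs a 3×3 linear part and 3-translation")
        det = np.linalg.det(self.linear)
        if abs(det) < 1e-12:
            raise ValidationError("affine linear part is singular")

    @property
    def scale(self) -> float:
        """Isotropic scale factor (cube root of the determinant magnitude)."""
        return float(abs(np.linalg.det(self.linear)) ** (1.0 / 3.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TemplateAtlas:
    """Reference-space CC mask plus the sagittal midline index."""

    cc_mask: BinaryVolume
    midline_index: int

    def __post_init__(self) -> None:
        if self.cc_mask.is_empty():
            raise ValidationError("template CC mask is empty")
        if not 0 <= self.midline_index < self.cc_mask.shape[0]:
            raise ValidationError("midline_index outside the template volume")


def _moments(vol: BinaryVolume) -> tuple[np.ndarray, np.ndarray]:
    coords = vol.world_coords()
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T, bias=True)
    return centroid, np.atleast_2d(cov)


def _principal_axes(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, E = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, E = lam[order], E[:, order]
    # fix eigenvector signs deterministically: largest-|component| positive
    for j in range(3):
        k = np.argmax(np.abs(E[:, j]))
        if E[k, j] < 0:
            E[:, j] = -E[:, j]
    if np.linalg.det(E) < 0:
        E[:, 2] = -E[:, 2]
    return lam, E


def affine_align(subject_wm: BinaryVolume, template: TemplateAtlas) -> AffineTransform:
    """Moments-based affine from subject space to template space.

    Matches centroids, principal axes, and per-axis second moments of the
    subject WM against the template CC mask.  Assumes roughly corresponding
    orientation (no flips), which holds for RAS-reoriented brain masks.
    """
    if subject_wm.is_empty():
        raise SegmentationError("subject WM mask is empty")
    c_s, cov_s = _moments(subject_wm)
    c_t, cov_t = _moments(template.cc_mask)
    lam_s, E_s = _principal_axes(cov_s)
    lam_t, E_t = _principal_axes(cov_t)
    if lam_s.min() <= 1e-9 * lam_s.max() or lam_t.min() <= 1e-12:
        raise SegmentationError(
            "degenerate second moments (planar or linear mass distribution)"
        )
    S = np.diag(np.sqrt(lam_t / lam_s))
    A = E_t @ S @ E_s.T
    b = c_t - A @ c_s
    return AffineTransform(A, b)


def _propagate_template_mask(
    template: TemplateAtlas, transform: AffineTransform, subject: BinaryVolume
) -> np.ndarray:
    """Resample the template CC mask onto the subject grid via the affine."""
    # voxel-space map: i_template = S_t^-1 (A (S_s i_s + o_s) + b - o_t)
    S_s = np.diag(subject.spacing)
    S_t_inv = np.diag(1.0 / template.cc_mask.spacing)
    M = S_t_inv @ transform.linear @ S_s
    off = S_t_inv @ (
        transform.linear @ subject.origin + transform.translation
        - template.cc_mask.origin
    )
    res = ndimage.affine_transform(
        template.cc_mask.voxels.astype(np.float32),
        matrix=M,
        offset=off,
        output_shape=subject.shape,
        order=1,
        cval=0.0,
    )
    return res >= 0.5


def segment_cc(
    subject_wm: BinaryVolume,
    template: TemplateAtlas,
    dilation_mm: float = 3.0,
    transform: AffineTransform | None = None,
) -> tuple[BinaryVolume, AffineTransform]:
    """Extract the CC from a WM mask by template-mask propagation.

    Returns the CC mask (always a subset of ``subject_wm``) and the affine
    used, whose scale normalises areas into template space downstream.
    """
    if dilation_mm < 0:
        raise ValidationError("dilation_mm must be ≥ 0")
    if transform is None:
        transform = affine_align(subject_wm, template)
    prop = _propagate_template_mask(template, transform, subject_wm)
    if dilation_mm > 0:
        dist = ndimage.distance_transform_edt(~prop, sampling=subject_wm.spacing)
        prop = dist <= dilation_mm
    cand = prop & subject_wm.voxels
    if not cand.any():
        raise SegmentationError("CC not found under mask")
    labels, n = ndimage.label(cand, structure=_STRUCT_3D)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        cand = labels == (1 + int(np.argmax(sizes)))
    cc = BinaryVolume(cand, subject_wm.spacing.copy(), subject_wm.origin.copy())
    return cc, transform


@dataclass
class SliceStack:
    """The midsagittal analysis slab: 2D masks plus their geometry."""

    slices: list[np.ndarray]
    indices: list[int]
    spacing: np.ndarray  # in-plane (Y, Z) mm
    origin: np.ndarray  # in-plane (Y, Z) mm of pixel (0, 0)
    empty_flags: list[bool]


def extract_midsagittal_slices(cc: BinaryVolume, n_slices: int = 7) -> SliceStack:
    """Select the ``n_slices`` adjacent sagittal slices for analysis.

    The slab is centred on the sagittal index of maximal CC cross-sectional
    area and clamped to the volume bounds.  When several adjacent indices
    tie for the maximum (a flat area profile), the centre of the tied set is
    used (lower median, i.e. the smaller index for a two-way tie), so a
    uniformly extruded CC yields its central slab.  Each slice is reduced to
    its largest 8-connected component; empty slices are flagged, never
    dropped.
    """
    if cc.is_empty():
        raise SegmentationError("CC volume is empty")
    if n_slices < 1 or n_slices % 2 == 0:
        raise ValidationError("n_slices must be a positive odd integer")
    areas = cc.voxels.sum(axis=(1, 2))
    nonempty = int((areas > 0).sum())
    if nonempty < n_slices:
        raise SegmentationError(
            f"only {nonempty} nonempty sagittal slices available, need {n_slices}"
        )
    tied = np.flatnonzero(areas == areas.max())
    centre = int(tied[(len(tied) - 1) // 2])
    half = n_slices // 2
    lo = centre - half
    lo = max(0, min(lo, cc.shape[0] - n_slices))
    idx = list(range(lo, lo + n_slices))

    slices, flags = [], []
    for i in idx:
        sl = cc.voxels[i]
        if sl.any():
            labels, n = ndimage.label(sl, structure=_STRUCT_2D)
            if n > 1:
                sizes = ndimage.sum_labels(
                    np.ones_like(labels), labels, np.arange(1, n + 1)
                )
                sl = labels == (1 + int(np.argmax(sizes)))
            slices.append(sl.copy())
            flags.append(False)
        else:
            slices.append(sl.copy())
            flags.append(True)
    return SliceStack(
        slices=slices,
        indices=idx,
        spacing=cc.spacing[1:].copy(),
        origin=cc.origin[1:].copy(),
        empty_flags=flags,
    )


def default_template(voxel_size: float = 1.0) -> TemplateAtlas:
    """The packaged reference atlas: a jitter-free half-annulus arch.

    Generated on demand (deterministic, seed-free geometry) so no image
    file ships with the package.
    """
    spec = CCShapeSpec(
        outer_radius=30.0,
        thickness=7.0,
        voxel_size=(voxel_size,) * 3,
        n_slices=9,
        boundary_jitter_sd=0.0,
        seed=0,
    )
    vol, _ = generate_cc_mask(spec)
    return TemplateAtlas(cc_mask=vol, midline_index=vol.shape[0] // 2)
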