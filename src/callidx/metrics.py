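"""Corpus-callosum index (CCI) and area (CCA) from midsagittal slices.

The CCI is the classic six-landmark thickness ratio measured on the
midsagittal CC outline:

    a  — most anterior point of the CC
    b  — most posterior point
    c  — boundary point farthest (perpendicular) from the line ab,
         on the superior side (the apex of the arch)
    a′, b′, c′ — the matching points on the opposite border

    CCI = (|aa′| + |bb′| + |cc′|) / |ab|

i.e. genu + splenium + body thickness over the greatest anteroposterior
diameter.  The opposite-border points are found by walking from a toward b
(and b toward a, and c toward the line ab) until the walk first leaves the
mask; walks are subpixel (0.1-pixel steps, bilinear occupancy, threshold
0.5) so thickness is not quantised to whole voxels.

Robustness over the seven analysis slices comes from aggregating the
*landmark coordinates* by their per-coordinate median and evaluating the
ratio once on the median landmarks — a single corrupted slice cannot move
the result.  CCA is the mean cross-sectional area over the slices, with a
template-normalised variant obtained via the squared affine scale.

Axis convention for 2D slices: array axis 0 = Y (posterior→anterior),
axis 1 = Z (inferior→superior); coordinates are world mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import LandmarkError, OpenBoundaryError, ValidationError
from .segmentation import AffineTransform, SliceStack

__all__ = [
    "SliceLandmarks",
    "CCIResult",
    "detect_landmarks",
    "cci_from_landmarks",
    "aggregate_cci",
    "compute_cca",
    "is_open_arch",
    "measure_stack",
]

_STRUCT_2D = np.ones((3, 3), dtype=bool)
_WALK_STEP_PX = 0.1
_MIN_PIXELS = 10


@dataclass
class SliceLandmarks:
    """The six CCI landmarks of one slice, world mm, (Y, Z) = (anterior, superior)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    a_prime: np.ndarray
    b_prime: np.ndarray
    c_prime: np.ndarray
    slice_index: int = -1

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def as_dict(self) -> dict[str, list[float]]:
        return {
            k: list(map(float, getattr(self, k)))
            for k in ("a", "b", "c", "a_prime", "b_prime", "c_prime")
        }

    def distances(self) -> dict[str, float]:
        return {
            "aa_prime": float(np.linalg.norm(self.a - self.a_prime)),
            "bb_prime": float(np.linalg.norm(self.b - self.b_prime)),
            "cc_prime": float(np.linalg.norm(self.c - self.c_prime)),
            "ab": float(np.linalg.norm(self.a - self.b)),
        }


# ---------------------------------------------------------------------------
# landmark detection
# ---------------------------------------------------------------------------


def _boundary_mask(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def _occupancy(mask_f: np.ndarray, px: np.ndarray) -> float:
    """Bilinear occupancy at fractional pixel coordinate ``px`` (2,)."""
    return float(
        ndimage.map_coordinates(
            mask_f, px.reshape(2, 1), order=1, mode="constant", cval=0.0
        )[0]
    )


def _walk_to_exit(
    mask_f: np.ndarray,
    start_mm: np.ndarray,
    direction: np.ndarray,
    spacing: np.ndarray,
    origin: np.ndarray,
) -> np.ndarray:
    """First point along ``direction`` where bilinear occupancy drops below 0.5."""
    u = direction / np.linalg.norm(direction)
    step = _WALK_STEP_PX * float(spacing.min())
    shape = np.asarray(mask_f.shape, dtype=float)
    max_len = float(np.linalg.norm(shape * spacing)) + 2 * step

    def occ_at(t: float) -> float:
        px = (start_mm + t * u - origin) / spacing
        return _occupancy(mask_f, px)

    if occ_at(0.0) < 0.5:
        raise LandmarkError("walk start point is outside the mask")
    t_prev, t = 0.0, step
    while t <= max_len:
        if occ_at(t) < 0.5:
            lo, hi = t_prev, t
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if occ_at(mid) >= 0.5:
                    lo = mid
                else:
                    hi = mid
            t_cross = 0.5 * (lo + hi)
            p = start_mm + t_cross * u
            px = (p - origin) / spacing
            if np.any(px < 0.0) or np.any(px > shape - 1.0):
                raise OpenBoundaryError(
                    "open boundary: walk left the image while inside the mask"
                )
            return p
        t_prev, t = t, t + step
    raise OpenBoundaryError("open boundary: walk never left the mask")


def _nearest_opposite(
    bpts_mm: np.ndarray, start_mm: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Nearest boundary point lying strictly in the walk direction (alt. rule)."""
    u = direction / np.linalg.norm(direction)
    rel = bpts_mm - start_mm
    ahead = rel @ u > 1e-9
    if not ahead.any():
        raise LandmarkError("no opposite-border point in the requested direction")
    d = np.linalg.norm(rel[ahead], axis=1)
    return bpts_mm[ahead][int(np.argmin(d))]


def detect_landmarks(
    slice2d: np.ndarray,
    spacing: tuple[float, float] | np.ndarray,
    origin: tuple[float, float] | np.ndarray = (0.0, 0.0),
    slice_index: int = -1,
    opposite: str = "walk",
) -> SliceLandmarks:
    """Detect the six CCI landmarks on one binary midsagittal slice.

    Parameters
    ----------
    slice2d
        2D boolean mask, one connected component, ≥ 10 foreground pixels.
    spacing, origin
        In-plane (Y, Z) pixel size and world position of pixel (0, 0), mm.
    opposite
        ``"walk"`` (default): opposite-border points by subpixel boundary
        walking.  ``"nearest"``: nearest boundary point in the walk
        direction — a coarser alternative kept for comparison.

    Tie rules (all deterministic): a maximises Y then Z then minimal raveled
    pixel index; b minimises Y with the same secondary rules; c maximises
    perpendicular distance to ab among boundary points strictly on the
    superior side of ab, ties toward the minimal index.
    """
    mask = np.asarray(slice2d) > 0.5 if np.asarray(slice2d).dtype != bool else np.asarray(slice2d)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if mask.ndim != 2:
        raise ValidationError("slice2d must be 2D")
    if int(mask.sum()) < _MIN_PIXELS:
        raise LandmarkError(f"too few foreground pixels ({int(mask.sum())} < {_MIN_PIXELS})")
    _, n_comp = ndimage.label(mask, structure=_STRUCT_2D)
    if n_comp != 1:
        raise LandmarkError(f"slice has {n_comp} connected components, expected 1")
    if opposite not in ("walk", "nearest"):
        raise ValidationError("opposite must be 'walk' or 'nearest'")

    boundary = _boundary_mask(mask)
    bidx = np.argwhere(boundary)  # C order → raveled-index order
    bpts = origin + bidx * spacing  # (n, 2) mm, columns (y, z)

    def extreme(maximize_y: bool) -> np.ndarray:
        ys = bpts[:, 0]
        sel = ys == (ys.max() if maximize_y else ys.min())
        cand = bpts[sel]
        zs = cand[:, 1]
        cand = cand[zs == zs.max()]
        return cand[0]  # bidx is in raveled order → first = minimal index

    a = extreme(True)
    b = extreme(False)
    d = b - a
    ab_len = float(np.linalg.norm(d))
    if ab_len <= 0:
        raise LandmarkError("a and b coincide")

    # superior normal to ab (for vertical ab, break toward anterior)
    n_vec = np.array([-d[1], d[0]])
    if n_vec[1] < 0 or (n_vec[1] == 0 and n_vec[0] < 0):
        n_vec = -n_vec
    n_hat = n_vec / np.linalg.norm(n_vec)
    sd = (bpts - a) @ n_hat
    sup = sd > 1e-9
    if not sup.any():
        raise LandmarkError("no boundary point superior to the line ab")
    sup_pts, sup_sd = bpts[sup], sd[sup]
    c = sup_pts[int(np.argmax(sup_sd))]  # argmax → minimal index on exact ties

    if opposite == "walk":
        mask_f = mask.astype(np.float64)
        a_p = _walk_to_exit(mask_f, a, d, spacing, origin)
        b_p = _walk_to_exit(mask_f, b, -d, spacing, origin)
        c_p = _walk_to_exit(mask_f, c, -n_hat, spacing, origin)
    else:
        a_p = _nearest_opposite(bpts, a, d)
        b_p = _nearest_opposite(bpts, b, -d)
        c_p = _nearest_opposite(bpts, c, -n_hat)

    return SliceLandmarks(a, b, c, a_p, b_p, c_p, slice_index=slice_index)


# ---------------------------------------------------------------------------
# CCI / CCA
# ---------------------------------------------------------------------------


def cci_from_landmarks(lm: SliceLandmarks) -> float:
    """CCI = (|aa′| + |bb′| + |cc′|) / |ab|."""
    d = lm.distances()
    if d["ab"] <= 0:
        raise LandmarkError("a and b coincide; CCI undefined")
    return (d["aa_prime"] + d["bb_prime"] + d["cc_prime"]) / d["ab"]


def is_open_arch(lm: SliceLandmarks) -> bool:
    """QC flag: the shape is not arch-like.

    On a closed arch the two end walks exit through the inner border, so
    their lengths sum to well below the anteroposterior diameter.  When a
    walk runs across the whole shape (e.g. a filled rectangle), the sum
    reaches |ab| and the CCI loses its meaning.
    """
    d = lm.distances()
    return d["aa_prime"] + d["bb_prime"] >= d["ab"] - 1e-9


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(np.asarray(values, dtype=float))
    return float(v[(len(v) - 1) // 2])


@dataclass
class CCIResult:
    """Aggregated CC morphometry for one subject."""

    per_slice_cci: list[float]
    per_slice_area_mm2: list[float]
    cci: float
    cca_mm2: float
    cca_template_normalized_mm2: float
    landmarks_median: SliceLandmarks
    n_slices_used: int
    slice_indices: list[int] = field(default_factory=list)
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cci": self.cci,
            "cca_mm2": self.cca_mm2,
            "cca_template_normalized_mm2": self.cca_template_normalized_mm2,
            "per_slice_cci": list(map(float, self.per_slice_cci)),
            "per_slice_area_mm2": list(map(float, self.per_slice_area_mm2)),
            "landmarks_median_mm": self.landmarks_median.as_dict(),
            "n_slices_used": self.n_slices_used,
            "slice_indices": list(self.slice_indices),
            "qc": self.qc,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def aggregate_cci(per_slice: list[SliceLandmarks]) -> tuple[float, SliceLandmarks, list[float]]:
    """Median-of-coordinates aggregation over slices.

    For each of the six landmarks the per-coordinate median across slices is
    taken (lower median for an even count, for determinism), and the CCI is
    evaluated once on the median landmarks.  Per-slice CCIs are returned for
    QC only.
    """
    if len(per_slice) == 0:
        raise LandmarkError("no valid slices to aggregate")
    med_pts = {}
    for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
        pts = np.array([getattr(lm, name) for lm in per_slice])
        med_pts[name] = np.array(
            [_lower_median(pts[:, 0]), _lower_median(pts[:, 1])]
        )
    lm_med = SliceLandmarks(**med_pts, slice_index=-1)
    per_slice_cci = [cci_from_landmarks(lm) for lm in per_slice]
    return cci_from_landmarks(lm_med), lm_med, per_slice_cci


def compute_cca(
    slices: list[np.ndarray],
    spacing: tuple[float, float] | np.ndarray,
    transform: AffineTransform | None = None,
) -> tuple[float, float]:
    """Mean CC cross-sectional area over the analysis slices, mm².

    Empty slices are excluded from the mean (they are QC failures, not
    anatomy).  The normalised variant multiplies by the squared isotropic
    affine scale, expressing the area in template space so head size
    differences cancel.
    """
    spacing = np.asarray(spacing, dtype=float)
    pixel_area = float(spacing[0] * spacing[1])
    areas = [float((np.asarray(s) > 0.5).sum()) * pixel_area for s in slices]
    nonzero = [a for a in areas if a > 0]
    if not nonzero:
        raise LandmarkError("all slices empty; CCA undefined")
    cca = float(np.mean(nonzero))
    scale = transform.scale if transform is not None else 1.0
    return cca, cca * scale**2


def measure_stack(
    stack: SliceStack,
    transform: AffineTransform | None = None,
    opposite: str = "walk",
) -> CCIResult:
    """Landmarks → CCI → CCA for one subject's midsagittal slab.

    Slices that are empty or where landmark detection fails are flagged in
    the QC record and excluded from aggregation; at least one slice must
    survive.
    """
    landmarks: list[SliceLandmarks] = []
    failures: dict[int, str] = {}
    open_flags: dict[int, bool] = {}
    for sl, idx, empty in zip(stack.slices, stack.indices, stack.empty_flags):
        if empty:
            failures[idx] = "empty slice"
            continue
        try:
            lm = detect_landmarks(
                sl, stack.spacing, stack.origin, slice_index=idx, opposite=opposite
            )
        except LandmarkError as exc:
            failures[idx] = str(exc)
            continue
        open_flags[idx] = is_open_arch(lm)
        landmarks.append(lm)
    if not landmarks:
        raise LandmarkError(
            f"no usable slice in slab {stack.indices}: {failures}"
        )
    cci, lm_med, per_slice_cci = aggregate_cci(landmarks)
    used = [lm.slice_index for lm in landmarks]
    area_slices = [s for s, e in zip(stack.slices, stack.empty_flags) if not e]
    cca, cca_norm = compute_cca(area_slices, stack.spacing, transform)
    areas = [
        float(np.asarray(s).sum()) * float(stack.spacing[0] * stack.spacing[1])
        for s in area_slices
    ]
    return CCIResult(
        per_slice_cci=per_slice_cci,
        per_slice_area_mm2=areas,
        cci=cci,
        cca_mm2=cca,
        cca_template_normalized_mm2=cca_norm,
        landmarks_median=lm_med,
        n_slices_used=len(landmarks),
        slice_indices=list(stack.indices),
        qc={
            "slice_failures": failures,
            "open_arch_flags": open_flags,
            "affine_scale": transform.scale if transform is not None else 1.0,
            "empty_slices": [
                i for i, e in zip(stack.indices, stack.empty_flags) if e
            ],
        },
    )
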