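"""Synthetic validation data: corpus-callosum arch phantoms and cohort tables.

The phantom is a half-annulus opening inferiorly — the region between
concentric semicircles of radii ``R`` (outer) and ``r = R − t·atrophy``
(inner), extruded across a block of sagittal slices.  It is deliberately a
geometric idealisation rather than an anatomical corpus callosum: the six
CCI landmarks (anterior tip, posterior tip, apex, and their opposite-border
partners) then have closed-form positions, so every downstream measurement
can be checked against analytic truth:

    CCI = 3 (R − r) / (2 R)        area per slice = π (R² − r²) / 2

Optional end bulbs thicken the arch near its anterior/posterior tips (the
genu/splenium analogue) by growing the local radial thickness; boundary
jitter is added in the signed-distance domain so small perturbations keep
the arch simply connected.

The cohort simulator draws per-group multivariate-Gaussian feature vectors
with specified means, SDs and correlation structure; the packaged defaults
are the printed summaries of a benign relapsing-remitting MS (BRRMS) group
versus healthy controls (HC): 35 subjects per group, CCI 0.31 (0.06) vs
0.37 (0.03), CCA 608.22 (116.51) vs 678.26 (87.61) mm², whole-brain tissue
904.37 (50.2) vs 919.47 (23.04) ml, and the reported within-group
correlations (CCI–CCA 0.738, CCI–brain 0.543, CCA–brain 0.532,
lesions–CCI −0.587, lesions–CCA −0.663 in the patient group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import CallidxError, ValidationError
from .volume import BinaryVolume

__all__ = [
    "CCShapeSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_cc_mask",
    "generate_wm_context",
    "generate_cohort",
    "default_cohort_spec",
    "bivariate_cohort_spec",
    "ancova_validation_spec",
    "COHORT_FEATURES",
    "GROUP_MEANS",
    "GROUP_SDS",
    "GROUP_CORR",
]

_BULB_SIGMA_RAD = 0.35  # angular width of the end-bulb thickening


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


@dataclass
class CCShapeSpec:
    """Parameters of a half-annulus CC phantom.

    All lengths in mm.  ``atrophy_factor`` multiplies the radial thickness
    (1.0 = no atrophy); ``bulb_scale`` ≥ 1 thickens the arch ends;
    ``boundary_jitter_sd`` is the SD (mm) of the smooth random perturbation
    added to the signed distance before thresholding.
    """

    outer_radius: float = 30.0
    thickness: float = 7.0
    bulb_scale: float = 1.0
    atrophy_factor: float = 1.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_slices: int = 9
    boundary_jitter_sd: float = 0.0
    seed: int = 0
    margin_mm: float = 12.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxel_size, dtype=float)
        if vox.shape == ():
            vox = np.repeat(float(vox), 3)
        if vox.shape != (3,) or np.any(vox <= 0):
            raise ValidationError("voxel_size must be 3 positive mm values")
        self.voxel_size = tuple(vox)
        if not 0 < self.atrophy_factor <= 1:
            raise ValidationError("atrophy_factor must be in (0, 1]")
        if self.bulb_scale < 1:
            raise ValidationError("bulb_scale must be ≥ 1")
        if self.thickness * self.atrophy_factor <= 2 * vox.max():
            raise ValidationError(
                "thickness × atrophy_factor must exceed 2 × max(voxel_size) "
                "(mask at least two voxels thick everywhere)"
            )
        if self.outer_radius <= self.thickness:
            raise ValidationError("outer_radius must exceed thickness")
        if self.n_slices < 7:
            raise ValidationError("n_slices must be ≥ 7")
        if self.boundary_jitter_sd < 0:
            raise ValidationError("boundary_jitter_sd must be ≥ 0")

    # local thickness of the arch at polar angle theta (0 = anterior tip)
    def thickness_at(self, theta: np.ndarray | float) -> np.ndarray | float:
        t = self.thickness * self.atrophy_factor
        if self.bulb_scale == 1.0:
            return t * np.ones_like(np.asarray(theta, dtype=float))
        bump = np.exp(-((np.asarray(theta, dtype=float) / _BULB_SIGMA_RAD) ** 2))
        bump = bump + np.exp(-(((np.pi - np.asarray(theta)) / _BULB_SIGMA_RAD) ** 2))
        return t * (1.0 + (self.bulb_scale - 1.0) * bump)


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated phantom.

    Landmark coordinates are in world mm, ``(y, z)`` = (anterior, superior),
    with the annulus centre at the world origin.
    """

    landmarks: dict[str, tuple[float, float]]
    cci: float
    area_per_slice_mm2: float
    outer_radius: float
    inner_radius_apex: float

    def to_dict(self) -> dict:
        return {
            "landmarks_mm": {k: list(v) for k, v in self.landmarks.items()},
            "cci": self.cci,
            "area_per_slice_mm2": self.area_per_slice_mm2,
            "outer_radius_mm": self.outer_radius,
            "inner_radius_apex_mm": self.inner_radius_apex,
        }


def _analytic_truth(spec: CCShapeSpec) -> PhantomTruth:
    R = spec.outer_radius
    t_ant = float(spec.thickness_at(0.0))
    t_post = float(spec.thickness_at(np.pi))
    t_apex = float(spec.thickness_at(np.pi / 2))
    landmarks = {
        "a": (R, 0.0),
        "b": (-R, 0.0),
        "c": (0.0, R),
        "a_prime": (R - t_ant, 0.0),
        "b_prime": (-(R - t_post), 0.0),
        "c_prime": (0.0, R - t_apex),
    }
    cci = (t_ant + t_post + t_apex) / (2 * R)
    theta = np.linspace(0.0, np.pi, 20001)
    t_th = np.asarray(spec.thickness_at(theta))
    area = float(np.trapezoid((2 * R * t_th - t_th**2) / 2.0, theta))
    return PhantomTruth(landmarks, cci, area, R, R - t_apex)


def generate_cc_mask(spec: CCShapeSpec) -> tuple[BinaryVolume, PhantomTruth]:
    """Voxelise a half-annulus arch phantom.

    Returns the binary volume (RAS; sagittal = axis 0) together with the
    analytic landmark positions, CCI and per-slice area.  The annulus centre
    sits at world ``(y, z) = (0, 0)`` and the arch opens toward −Z.
    """
    R = spec.outer_radius
    dx, dy, dz = spec.voxel_size
    m = spec.margin_mm

    pad_x = int(np.ceil(m / dx))
    nx = spec.n_slices + 2 * pad_x
    ny = int(np.ceil(2 * (R + m) / dy))
    nz = int(np.ceil((R + 2 * m) / dz))
    origin = np.array(
        [
            -(nx * dx) / 2 + dx / 2,
            -(ny * dy) / 2 + dy / 2,
            -m + dz / 2,
        ]
    )

    y = origin[1] + np.arange(ny) * dy
    z = origin[2] + np.arange(nz) * dz
    Y, Z = np.meshgrid(y, z, indexing="ij")
    rho = np.hypot(Y, Z)
    theta = np.arctan2(np.maximum(Z, 0.0), Y)
    r_inner = R - np.asarray(spec.thickness_at(theta))
    # signed distance: negative inside the half-annulus
    sdf2d = np.maximum.reduce([rho - R, r_inner - rho, -Z])

    voxels = np.zeros((nx, ny, nz), dtype=bool)
    arch = slice(pad_x, pad_x + spec.n_slices)
    if spec.boundary_jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal((nx, ny, nz))
        noise = ndimage.gaussian_filter(noise, sigma=1.5)
        noise *= spec.boundary_jitter_sd / noise.std()
        voxels[arch] = (sdf2d[None, :, :] + noise[arch]) < 0
    else:
        voxels[arch] = sdf2d[None, :, :] < 0

    vol = BinaryVolume(voxels, np.array([dx, dy, dz]), origin)
    return vol, _analytic_truth(spec)


def generate_wm_context(
    cc: BinaryVolume,
    spec: CCShapeSpec,
    n_distractors: int = 3,
    distractor_radius_mm: float = 3.0,
    clearance_mm: float = 6.0,
    max_attempts: int = 200,
) -> BinaryVolume:
    """Embed the CC phantom in a white-matter volume with distractor blobs.

    Distractor spheres are placed so their surfaces stay at least
    ``clearance_mm`` from the CC (twice the default dilation margin of the
    segmentation stage), giving the mask-propagation step non-CC structures
    it must reject.  CC voxels are never modified.
    """
    if cc.is_empty():
        raise ValidationError("cc volume is empty")
    out = cc.voxels.copy()
    if n_distractors == 0:
        return BinaryVolume(out, cc.spacing.copy(), cc.origin.copy())

    dist_to_cc = ndimage.distance_transform_edt(~cc.voxels, sampling=cc.spacing)
    rng = np.random.default_rng(spec.seed + 104729)
    shape = np.array(cc.shape)
    idx = np.indices(cc.shape)

    for k in range(n_distractors):
        for attempt in range(max_attempts):
            centre = np.array([rng.integers(0, s) for s in shape])
            edge_mm = np.minimum(centre, shape - 1 - centre) * cc.spacing
            if edge_mm.min() < distractor_radius_mm:
                continue
            if dist_to_cc[tuple(centre)] < clearance_mm + distractor_radius_mm:
                continue
            d2 = sum(
                ((idx[a] - centre[a]) * cc.spacing[a]) ** 2 for a in range(3)
            )
            out |= d2 <= distractor_radius_mm**2
            break
        else:
            raise CallidxError(
                f"could not place distractor {k + 1}/{n_distractors} after "
                f"{max_attempts} attempts; reduce clearance or count"
            )
    return BinaryVolume(out, cc.spacing.copy(), cc.origin.copy())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

COHORT_FEATURES = ["brain_tissue_ml", "cci", "cca_mm2", "wm_lesion_ml"]

#: Printed group summaries (mean, SD) for the default two-group cohort.
#: Patient lesion load is the pooled moment of the treated/untreated
#: subgroups; control lesion load is a small nominal value (healthy WM).
GROUP_MEANS: Mapping[str, np.ndarray] = {
    "BRRMS": np.array([904.37, 0.31, 608.22, 16.88]),
    "HC": np.array([919.47, 0.37, 678.26, 0.5]),
}
GROUP_SDS: Mapping[str, np.ndarray] = {
    "BRRMS": np.array([50.2, 0.06, 116.51, 12.9]),
    "HC": np.array([23.04, 0.03, 87.61, 0.3]),
}
# order: brain_tissue, cci, cca, wm_lesion.  The brain–lesion entry is not
# reported for the patient group; −0.45 keeps the matrix positive definite.
GROUP_CORR: Mapping[str, np.ndarray] = {
    "BRRMS": np.array(
        [
            [1.0, 0.543, 0.532, -0.45],
            [0.543, 1.0, 0.738, -0.587],
            [0.532, 0.738, 1.0, -0.663],
            [-0.45, -0.587, -0.663, 1.0],
        ]
    ),
    "HC": np.array(
        [
            [1.0, 0.1, -0.007, 0.0],
            [0.1, 1.0, 0.1, 0.0],
            [-0.007, 0.1, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    ),
}


@dataclass
class CohortSpec:
    """Two-group multivariate-Gaussian cohort description.

    ``group_means``/``group_sds`` are ``(2, p)`` arrays (row per group in
    ``group_labels`` order); ``group_corr`` is ``(2, p, p)``.  Feature
    columns named in ``clip_nonnegative`` are floored at zero after drawing
    (physical volumes cannot be negative).
    """

    n_per_group: int
    feature_names: list[str]
    group_means: np.ndarray
    group_sds: np.ndarray
    group_corr: np.ndarray
    group_labels: tuple[str, str] = ("BRRMS", "HC")
    clip_nonnegative: tuple[str, ...] = ()
    add_demographics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        self.group_means = np.atleast_2d(np.asarray(self.group_means, float))
        self.group_sds = np.atleast_2d(np.asarray(self.group_sds, float))
        self.group_corr = np.asarray(self.group_corr, float)
        if self.group_corr.ndim == 2:
            self.group_corr = np.stack([self.group_corr] * 2)
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be ≥ 1")
        if self.group_means.shape != (2, p) or self.group_sds.shape != (2, p):
            raise ValidationError("group_means/group_sds must be (2, n_features)")
        if np.any(self.group_sds <= 0):
            raise ValidationError("all SDs must be > 0")
        if self.group_corr.shape != (2, p, p):
            raise ValidationError("group_corr must be (2, n_features, n_features)")
        for g, C in zip(self.group_labels, self.group_corr):
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValidationError(f"correlation matrix for {g} not symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-10):
                raise ValidationError(f"correlation matrix for {g} lacks unit diagonal")
            lam = np.linalg.eigvalsh(C).min()
            if lam < -1e-10:
                raise ValidationError(
                    f"correlation matrix for {g} is not positive semi-definite "
                    f"(smallest eigenvalue {lam:.3g})"
                )


def _corr_sqrt(C: np.ndarray) -> np.ndarray:
    """Cholesky factor, falling back to an eigen square root for PSD-singular C."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        lam, E = np.linalg.eigh(C)
        return E * np.sqrt(np.clip(lam, 0.0, None))


# demographic generating parameters: ~80% female in both groups, mean age 51
# (range 32–70), patient disease duration ~18 y (≥ 10 by definition of the
# benign phenotype), 23/35 on disease-modifying treatment, 40% of patient
# scans Gd-enhanced, EDSS ≤ 3 with median 2, relapse count median ~4.
_EDSS_LEVELS = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
_EDSS_WEIGHTS = np.array([0.05, 0.08, 0.12, 0.15, 0.30, 0.18, 0.12])


def _demographics(rng: np.random.Generator, n: int, group: str, patient_label: str) -> dict:
    cols: dict[str, np.ndarray] = {}
    cols["age"] = np.clip(np.round(rng.normal(51.0, 9.3, n), 1), 26.0, 70.0)
    n_f = int(round(0.8 * n))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    cols["sex"] = rng.permutation(sex)
    if group == patient_label:
        cols["disease_duration"] = np.clip(
            np.round(rng.normal(18.2, 5.1, n), 1), 10.0, 33.0
        )
        n_dmt = int(round(n * 23 / 35))
        cols["dmt"] = rng.permutation(np.array([1] * n_dmt + [0] * (n - n_dmt)))
        cols["gd_flag"] = (rng.random(n) < 0.4).astype(int)
        cols["edss"] = rng.choice(_EDSS_LEVELS, size=n, p=_EDSS_WEIGHTS / _EDSS_WEIGHTS.sum())
        cols["relapse_count"] = np.clip(rng.poisson(4.0, n), 1, 10)
    else:
        cols["disease_duration"] = np.full(n, np.nan)
        cols["dmt"] = np.zeros(n, dtype=int)
        cols["gd_flag"] = np.zeros(n, dtype=int)
        cols["edss"] = np.full(n, np.nan)
        cols["relapse_count"] = np.full(n, np.nan)
    return cols


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a reproducible two-group cohort table.

    One row per subject; columns ``subject_id``, ``group``, demographics,
    then the feature columns.  Identical spec (including seed) gives a
    bit-identical table.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for gi, label in enumerate(spec.group_labels):
        L = _corr_sqrt(spec.group_corr[gi])
        z = rng.standard_normal((spec.n_per_group, len(spec.feature_names)))
        X = spec.group_means[gi] + (z @ L.T) * spec.group_sds[gi]
        df = pd.DataFrame(X, columns=spec.feature_names)
        for name in spec.clip_nonnegative:
            if name in df:
                df[name] = df[name].clip(lower=0.0)
        df.insert(0, "group", label)
        df.insert(
            0,
            "subject_id",
            [f"{label}_{i:03d}" for i in range(spec.n_per_group)],
        )
        if spec.add_demographics:
            demo = _demographics(
                rng, spec.n_per_group, label, spec.group_labels[0]
            )
            for k, v in demo.items():
                df[k] = v
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def default_cohort_spec(n_per_group: int = 35, seed: int = 0) -> CohortSpec:
    """The packaged BRRMS-vs-HC cohort at the printed group summaries."""
    return CohortSpec(
        n_per_group=n_per_group,
        feature_names=list(COHORT_FEATURES),
        group_means=np.stack([GROUP_MEANS["BRRMS"], GROUP_MEANS["HC"]]),
        group_sds=np.stack([GROUP_SDS["BRRMS"], GROUP_SDS["HC"]]),
        group_corr=np.stack([GROUP_CORR["BRRMS"], GROUP_CORR["HC"]]),
        clip_nonnegative=("wm_lesion_ml",),
        seed=seed,
    )


def ancova_validation_spec(
    effect: float,
    n_per_group: int = 35,
    seed: int = 0,
    rho: float = 0.5,
    covariate_shift: float = 1.0,
) -> CohortSpec:
    """Cohort with a known *adjusted* group effect, for CI calibration runs.

    Outcome and covariate are jointly Gaussian with correlation ``rho`` and
    unit SDs in both groups; the covariate mean is shifted by
    ``covariate_shift`` in the first group (a confounder), and the outcome
    mean by ``effect + rho·covariate_shift`` so that the covariate-adjusted
    group difference is exactly ``effect``.  The generating process matches
    the ANCOVA model assumptions (linear, homoscedastic), so the 95% CI
    from :func:`callidx.stats.ancova_difference` has nominal coverage.
    """
    C = np.array([[1.0, rho], [rho, 1.0]])
    return CohortSpec(
        n_per_group=n_per_group,
        feature_names=["outcome", "covariate"],
        group_means=np.array(
            [[effect + rho * covariate_shift, covariate_shift], [0.0, 0.0]]
        ),
        group_sds=np.ones((2, 2)),
        group_corr=np.stack([C, C]),
        add_demographics=False,
        seed=seed,
    )


def bivariate_cohort_spec(
    rho: float,
    n_per_group: int,
    seed: int = 0,
    names: tuple[str, str] = ("x", "y"),
    means: tuple[float, float] = (0.0, 0.0),
    sds: tuple[float, float] = (1.0, 1.0),
) -> CohortSpec:
    """Two features at a single target correlation in both groups.

    Convenience for correlation-recovery experiments; no clipping, no
    demographics.
    """
    C = np.array([[1.0, rho], [rho, 1.0]])
    return CohortSpec(
        n_per_group=n_per_group,
        feature_names=list(names),
        group_means=np.stack([np.asarray(means), np.asarray(means)]),
        group_sds=np.stack([np.asarray(sds), np.asarray(sds)]),
        group_corr=np.stack([C, C]),
        add_demographics=False,
        seed=seed,
    )
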