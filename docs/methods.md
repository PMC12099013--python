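# Methods

## The measurement

`callidx` measures corpus-callosum (CC) atrophy on the midsagittal plane of
a binary segmentation. All volumes are reoriented to RAS (axis 0 sagittal,
+Y anterior, +Z superior) before any geometry is computed, so the landmark
semantics are defined in one fixed anatomical frame.

**Segmentation.** The subject's white-matter (WM) mask is aligned to a
template space by a moments-based affine: centroid translation, principal
axes from the second-moment eigenvectors (signs fixed deterministically,
right-handed), and per-axis scales from the eigenvalue ratios. The template
CC mask is propagated to subject space through the inverse affine (linear
resampling, threshold 0.5), dilated by a metric margin honouring
anisotropic voxel spacing (Euclidean distance transform, default **3 mm**),
intersected with the WM mask, and reduced to its largest 26-connected
component. The affine-plus-margin design is a deliberate simplification of
a non-rigid registration step: the intersection with the subject's own WM
defines the final boundary, so the propagated mask only needs to *cover*
the CC, not trace it. The cost is that the margin must absorb all residual
misalignment — structures closer to the CC than the margin are excluded
only if they are not connected to it within the WM mask.

**Slab selection.** Seven adjacent sagittal slices are analysed, centred on
the index of maximal CC cross-sectional area. When several indices tie for
the maximum (flat profile, as with an extruded phantom), the centre of the
tied run is used — the lower median of the argmax set, which reduces to the
smaller index for a two-way tie. Each slice is reduced to its largest
8-connected component; empty slices are flagged and excluded from
aggregation, never silently dropped.

**Landmarks.** Per slice, on the boundary (foreground pixels with a
4-neighbour background):

* `a` — maximal Y; ties broken by maximal Z, then minimal raveled index;
* `b` — minimal Y, same secondary rules;
* `c` — maximal perpendicular distance to the line `ab`, restricted to
  points strictly on the superior side (the arch apex; the restriction
  stops rostrum-like inferior protrusions from winning), ties toward the
  minimal index;
* `a′`, `b′`, `c′` — the first point where a walk from `a` along
  `(b−a)/|b−a|` (resp. from `b` along the opposite direction, from `c`
  along the inward normal of `ab`) leaves the mask. Walks advance in
  0.1-pixel steps with bilinear occupancy, "inside" meaning occupancy
  ≥ 0.5, and the crossing is refined by 40 bisection steps, so thickness is
  not quantised to whole voxels. A walk that reaches the image border while
  still inside raises an "open boundary" error.

A nearest-boundary-point alternative for the primes is available
(`opposite="nearest"`) but not default: on smooth arcs it latches onto the
adjacent outer rim instead of the opposite border and underestimates
thickness (demonstrated in the test suite).

**Aggregation.** The per-coordinate median of each landmark across the
usable slices (lower median for an even count, for determinism) defines the
median landmark set, and

```
CCI = (|aa′| + |bb′| + |cc′|) / |ab|
```

is evaluated once on it. With ≥ 4 intact slices of 7, a corrupted minority
cannot move any median coordinate, so the aggregate is exactly the
clean-slice value. Per-slice CCIs are reported for QC only. A per-slice
open-arch flag (`|aa′| + |bb′| ≥ |ab|`) marks shapes where an end walk
crossed the whole mask — the CCI is meaningless on non-arch topology.

**CCA.** Mean foreground area (pixel count × pixel area) over the non-empty
slab slices, in mm². The template-normalised variant multiplies by the
squared isotropic affine scale (cube root of the linear-part determinant),
cancelling global head-size differences.

## Quantisation behaviour

The extreme-point landmarks are anchored to the anatomical Y axis, with two
consequences worth knowing:

* On a shape whose anterior extreme is a smooth arc, the discrete
  "most-anterior column" spans ≈ √(2·R·voxel) in Z (1.4 mm at R = 10 mm
  and 0.25 mm voxels); the max-Z tie rule picks its top. Distances
  (`|aa′|`, `|ab|`, …) stay voxel-accurate, but landmark *positions* are
  tangentially ill-conditioned, and boundary jitter biases the computed CCI
  upward by a few voxel widths of `|ab|` (≈ +0.03 at 1 mm voxels with
  0.3 mm jitter). Group contrasts are unaffected to first order since both
  groups share the bias.
* The measurement is rotation-invariant only while the rotation does not
  reassign which physical boundary points are the AP extremes. An exact
  half-annulus has its arch ends precisely at the extremes, so any rotation
  moves one extreme onto the arc interior; arcs extending past the
  half-circle are rotation-invariant in all four distances (tested).

Jitter-free half-annulus phantoms recover the closed-form CCI within two
voxel-quantisation widths of the ratio (2·voxel/2R), and the per-slice area
within 2% across resolutions.

## The phantom family

`CCShapeSpec` voxelises the region between concentric semicircles of radii
`R = outer_radius` (default **30 mm**) and `r = R − thickness·atrophy_factor`
(thickness default **7 mm**), opening inferiorly, extruded over `n_slices`
(default 9) sagittal slices — sized so defaults give CCI 0.35 and
≈ 583 mm² per slice, inside the adult range. Optional end bulbs
(`bulb_scale` ≥ 1) thicken the arch near its tips (genu/splenium analogue)
by locally growing the radial thickness with Gaussian angular profiles
(σ = 0.35 rad). Boundary jitter is a smooth Gaussian random field
(σ = 1.5 voxels correlation) added to the *signed distance* before
thresholding, scaled to `boundary_jitter_sd` mm — perturbing the boundary
while keeping small-jitter masks simply connected. Because the jitter field
depends only on the grid and the seed, thinning the arch
(`atrophy_factor` < 1) produces a strict voxel subset of the unthinned
phantom at the same seed.

Closed forms: `CCI = 3(R−r)/(2R)` for the plain arch (with bulbs, the
end/apex thicknesses enter the same three-term sum), per-slice area
`π(R²−r²)/2` (quadrature of the angular thickness profile with bulbs).
`generate_wm_context` embeds the CC in a WM volume with distractor spheres
kept ≥ 6 mm (twice the dilation margin) clear of the CC, giving the
propagation step structures it must reject.

The phantom deliberately does **not** emulate a real CC spline shape,
rostrum, partial-volume effects, MRI intensities, bias fields, or scanner
differences. Passing phantom tests therefore demonstrates the geometric
correctness and robustness of the landmark/aggregation machinery, not
performance on clinical segmentations.

## The cohort simulator

`generate_cohort` draws per-group multivariate-Gaussian feature vectors
(Cholesky factor of the correlation matrix, scaled by the SDs) plus
demographic columns. The packaged default is a 35 + 35 benign
relapsing-remitting MS (BRRMS) vs healthy-control (HC) study at the
published group summaries:

| feature            | BRRMS mean (SD)   | HC mean (SD)     |
|--------------------|-------------------|------------------|
| brain_tissue_ml    | 904.37 (50.2)     | 919.47 (23.04)   |
| cci                | 0.31 (0.06)       | 0.37 (0.03)      |
| cca_mm2            | 608.22 (116.51)   | 678.26 (87.61)   |
| wm_lesion_ml       | 16.88 (12.9)      | 0.5 (0.3)        |

Patient-group correlations: CCI–CCA 0.738, CCI–brain 0.543, CCA–brain
0.532, lesions–CCI −0.587, lesions–CCA −0.663. The brain–lesion entry is
not published; it is fixed at −0.45, which keeps the matrix positive
definite alongside the five published values. The patient lesion mean/SD
are pooled moments of the published treated/untreated subgroup summaries;
the control value is a small nominal load. Control correlations are near
zero (brain–CCA −0.007 as published). Lesion volumes are floored at zero
after drawing (physical volumes; the induced distortion at these parameters
is negligible for patients and documented rather than modelled). EDSS is
drawn from a discrete 0–3 grid with median 2, relapse counts from a Poisson
clipped to 1–10, disease duration ≥ 10 y — matching published medians and
ranges for the benign phenotype; sex is exactly 80% female per group and
40% of patient scans carry the Gd flag. Identical specs (including seed)
give bit-identical tables.

## Statistics

`ancova_difference` fits `outcome ~ 1 + group + covariates` by OLS and
reports the group coefficient (patients-minus-controls coding by default),
its t-based 95% CI and two-sided p — classic homoscedastic ANCOVA, matching
standard clinical-statistics practice; no robust/Welch variant. With no
covariates the estimate equals the raw difference of means to machine
precision. Collinear design columns raise an error naming the dependency;
an outcome fully explained by the covariates (zero-residual fit, detected
at float-noise level) returns estimate 0, p = 1 and a zero-width CI rather
than an indeterminate t-ratio. Missing data are handled complete-case per
analysis, with the dropped count reported. No multiplicity correction is
applied by default; `batch_ancova(..., fdr=True)` adds Benjamini–Hochberg
adjusted p-values.

**CI calibration.** `ancova_validation_spec` defines the coverage
experiment: outcome and covariate jointly Gaussian (ρ = 0.5, unit SDs in
both groups), covariate shifted +1 SD in the patient group (a true
confounder), outcome mean offset so the covariate-adjusted difference is
exactly the nominal effect. This generating process satisfies the ANCOVA
model, so the 95% CI is exactly calibrated; measured coverage over 1000
cohorts of 35 + 35 is ~95%. Note that the published *feature* summaries are
strongly heteroscedastic across groups (CCI SD 0.06 vs 0.03); with equal
group sizes the point estimate and CI remain nearly nominal, but a
covariate that varies in only one group (like the Gd flag) pushes coverage
a few points below nominal under such heteroscedasticity — a known limit of
the homoscedastic model, inherited by design.

`pearson_by_group` is the plain Pearson correlation on complete cases
within one group (exact t-based two-sided p); `compare_demographics` wraps
Student's t (pooled variance), Mann-Whitney U (two-sided), and chi-square
on 2×k tables *without* continuity correction. `residualize` returns the
OLS residual plus the grand mean — a transparent linear stand-in for
normative covariate adjustment: mean-preserving, zero partial correlation
with each covariate by construction.

## Problem sizes and determinism

Validation runs are sized for interactive use: analytic phantoms at 0.25 mm
voxels (R = 10 mm), pipeline phantoms at 1 mm (R = 30 mm) with 5 subjects
per group, brute-force landmark cross-checks on 50 shapes ≤ 64×64,
cohort-recovery at 500 replicates of 35 + 35 plus single 100 000-subject
draws, and CI coverage over 1000 cohorts. Every stochastic component takes
an explicit integer seed; pipelines rerun byte-identically under a fixed
config.

## Known limitations

* Moments-based affine alignment assumes the subject and template masks
  have comparable mass distributions and no axis flips; distractor
  structures shift the subject moments slightly, which the dilation margin
  must absorb (alignment scale on WM-context phantoms reads ~0.85–0.95
  against the CC-only template — harmless to the segmentation but the
  normalised CCA inherits that convention).
* The anatomical-frame landmark definition is not equivariant under large
  in-plane rotations of pathological shapes (see quantisation notes); real
  midsagittal CCs are measured in a consistent head orientation, as here.
* Boundary jitter inflates CCI slightly through the extreme-point tie
  rules; absolute CCI values carry a resolution-dependent bias of a few
  voxel widths of |ab| while group contrasts remain valid.
* Gaussian cohort features reproduce published first/second moments and
  correlations, not distributional shape, outliers, or missingness
  patterns of real cohorts.
* No intensity-based WM segmentation, lesion handling, non-rigid
  registration, or DICOM ingestion — inputs are binary NIfTI masks.
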