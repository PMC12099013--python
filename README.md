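# callidx

Automated **corpus-callosum index (CCI)** and **corpus-callosum area (CCA)**
morphometry from binary brain segmentations, plus the two-group statistics
used in brain-atrophy cohort studies (multiple sclerosis vs healthy
controls), and a synthetic phantom/cohort harness that makes the whole
pipeline testable against analytic ground truth.

## What it computes

The corpus callosum (CC) thins early in demyelinating disease. The CCI is
the classic midsagittal thickness ratio over six landmarks on the CC
outline — **a** (most anterior point), **b** (most posterior point), **c**
(boundary point farthest from the line *ab*, superior side), and their
opposite-border partners **a′, b′, c′**:

```
CCI = (|aa′| + |bb′| + |cc′|) / |ab|
```

i.e. genu + splenium + body thickness divided by the greatest
anteroposterior diameter (dimensionless, ≈ 0.25–0.40 in adults). The CCA is
the CC cross-sectional area (mm²) on the midsagittal slices.

The pipeline mirrors an automated clinical workflow:

1. **Segmentation** — a subject white-matter (WM) mask is aligned to a
   template space with a moments-based affine; the template CC mask is
   propagated back, dilated by a metric margin (default 3 mm), intersected
   with the WM mask, and reduced to its largest connected component.
2. **Slab selection** — seven adjacent sagittal slices centred on the
   maximal CC cross-section are analysed independently.
3. **Landmarks & metrics** — the six landmarks are detected per slice
   (subpixel boundary walks for the opposite-border points); the final CCI
   uses the per-coordinate **median** of the landmarks across the seven
   slices, so single-slice failures cannot move the result. CCA is the mean
   slice area, with a template-normalised variant via the squared affine
   scale.
4. **Statistics** — ANCOVA adjusted group differences with 95% CIs
   (OLS, patients-minus-controls coding), within-group Pearson
   correlations, and t / Mann-Whitney / chi-square demographic tests.

Because no patient data ship with the package, validation runs on
**half-annulus arch phantoms** with closed-form truth
(`CCI = 3(R−r)/(2R)`, area `π(R²−r²)/2`) and on **simulated cohorts**
drawn at published group summaries (CCI 0.31 ± 0.06 in benign
relapsing-remitting MS vs 0.37 ± 0.03 in controls, CCA 608 ± 117 vs
678 ± 88 mm², and their within-group correlation structure).

## Worked example

```python
from callidx import (CCShapeSpec, generate_cc_mask, generate_wm_context,
                     default_template, analyze_subject)

spec = CCShapeSpec(outer_radius=30, thickness=7, atrophy_factor=0.8,
                   boundary_jitter_sd=0.3, seed=42)
cc, truth = generate_cc_mask(spec)          # phantom CC + analytic truth
wm = generate_wm_context(cc, spec)          # embed in WM with distractors
res = analyze_subject(wm, default_template())
print(f"CCI  {res.cci:.3f}   (analytic truth {truth.cci:.3f})")
print(f"CCA  {res.cca_mm2:.1f} mm2  (analytic truth {truth.area_per_slice_mm2:.1f})")
```

```
CCI  0.309   (analytic truth 0.280)
CCA  487.9 mm2  (analytic truth 478.5)
```

The computed CCI sits within the voxel-quantisation band of the analytic
value (boundary jitter and the discrete anterior/posterior extrema bias the
ratio upward by a few voxel widths of |ab|; see `docs/methods.md`), and the
measured area is within 2% of the closed form.

Cohort statistics on a simulated 35 + 35 study at the published summaries:

```python
from callidx import (default_cohort_spec, generate_cohort,
                     ancova_difference, pearson_by_group)
df = generate_cohort(default_cohort_spec(35, seed=1))
print(ancova_difference(df, "cci", ["gd_flag"]))
print(pearson_by_group(df, "cci", "cca_mm2", "BRRMS"))
```

```
cci: BRRMS − HC = -0.05045 (95% CI -0.07666; -0.02424), p = 0.000274 [adjusted for: gd_flag; n = 35/35]
cci vs cca_mm2 in BRRMS: r = 0.768, p = 7.11e-08, n = 35
```

The adjusted difference recovers the generating −0.06 gap within sampling
noise, and the CCI–CCA correlation matches the generating value 0.738
within its n = 35 sampling band.

## Command line

```bash
callidx simulate --out study/ --n-per-group 5 --seed 1
callidx extract  --wm study/BRRMS_000_wm.nii.gz --out cc.nii.gz
callidx cci      --cc cc.nii.gz --slices 7 --out metrics.json
callidx stats    --table cohort.csv --outcome cci --covariates gd_flag --out stats.csv
callidx run      --config pipeline.yaml
```

## Layout

```
src/callidx/
  synthetic.py      arch phantoms + cohort simulator (analytic truth)
  segmentation.py   moments affine, template propagation, slab selection
  metrics.py        landmark detection, CCI, median aggregation, CCA
  stats.py          ANCOVA, correlations, demographics, residualisation
  pipeline.py       end-to-end runs, phantom-study simulation
  volume.py, cli.py, plotting.py
docs/methods.md     model, parameters, numerical choices, limitations
```
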