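# perivene

Volumetry of the contrast-enhanced space surrounding the diploic veins and of
the parasagittal dura (PSD) on 3D contrast-enhanced head MRI, together with
intracranial-volume (ICV) correction and the accompanying cohort statistics.
Every stage is driven and validated by a synthetic cranial-phantom and
synthetic-cohort generator, so the full pipeline is testable without any
patient data.

## What it does

- **image_io** — NIfTI-1 reading/writing (RAS-canonical on load), binary-mask
  handling, voxel-count → mm³ conversion.
- **phantom_generator** — synthetic heads with ground-truth masks and volumes
  (skull shell with a diploe carrying high-signal-sheathed, dark-lumen
  vein tubes; a dark midline sinus flanked by high-signal dural blobs; a brain
  ellipsoid), plus calibrated synthetic cohorts (log-normal marginals,
  Gaussian-copula age dependence) and two-rater measurement tables.
- **icv_estimation** — a documented surrogate for external brain-extraction
  tools: threshold (fixed or Otsu) → largest 26-connected component →
  morphological closing → hole fill.
- **perivenous_segmentation** — threshold → exclusion-mask subtraction →
  restriction to slices strictly above the lateral-ventricle plane →
  removal of in-plane components with maximum inscribed-disc diameter
  < 2 mm (anisotropy-aware EDT, inclusive at the boundary).
- **psd_segmentation** — threshold → 10 mm 3D Euclidean band from the outer
  edge of the superior sagittal sinus → slice restriction → brain/skull
  mask subtraction.
- **cohort_statistics** — ICV correction (mm³ cm⁻³), Lilliefors-corrected
  KS normality gating, Pearson/Spearman correlation (exact permutation p for
  n ≤ 10), Welch t / Mann–Whitney U (exact for min(n,m) ≤ 8 without ties),
  ICC(2,1) with F-based 95% CI on Ln(x+1)-transformed volumes, and a full
  per-cohort analysis report.

Calibration constants for the generators live in
`src/perivene/data/calibration.yaml` (single versioned source of truth).

## CLI

```bash
perivene phantom --seed 1 --out phantom/                # image + truth masks + truth.json
perivene cohort  --seed 1 --out cohort.csv              # synthetic cohort table
perivene icv --image phantom/image.nii.gz --threshold 80 --out icv.json
perivene segment-dv --image phantom/image.nii.gz --threshold 130 --zmin 60 \
    --exclude phantom/mask_psd.nii.gz --out dv.json
perivene segment-psd --image phantom/image.nii.gz --sss phantom/mask_sss.nii.gz \
    --brain phantom/mask_brain.nii.gz --skull phantom/mask_skull.nii.gz \
    --threshold 130 --zmin 60 --out psd.json
perivene stats --cohort cohort.csv --out report.json
perivene icc --table raters.csv --transform ln1p --out icc.json
```

Cohort CSV columns: `id, age, sex (M/F), dv_volume (mm³), psd_volume (mm³),
icv (cm³)`.

## Notes and conventions

- "Above the superior border of the lateral ventricles" is strict: the border
  slice itself is excluded.
- The ≥ 2 mm diameter criterion is evaluated per transverse slice
  (8-connected, physical-spacing EDT); a 3D variant is available via
  `diameter_mode="3d"`.
- The segmentation intensity threshold is always an explicit input; an Otsu
  helper over a chosen compartment exists but is never applied silently.
- Cohort volume marginals are log-normal (an assumption — only medians, IQRs
  and non-normality are known); noise is Gaussian, not Rician.
- The ICV routine is a surrogate for a deformable-surface brain-extraction
  tool, intended to provide a consistent denominator, not to reproduce any
  specific third-party tool.
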