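# Methods

## The scoring model

Arterial calcium load on CT is conventionally quantified on noncontrast
scans by thresholding at 130 HU. On contrast-enhanced CT the opacified
blood pool itself exceeds 130 HU, so this package implements the
patient-specific alternative: the mean attenuation μ and sample SD σ of
the blood pool are measured in two axial regions of interest drawn inside
the aortic lumen (one near the celiac trunk, one just above the aortic
bifurcation), each ROI yields μ + 3σ, and the larger of the two values is
the segmentation threshold. The aortic wall is never part of the ROI
sample; the ROIs must be drawn inside the lumen.

Voxels at or above the threshold (inclusive comparison, matching the
130 HU Agatston convention) and inside a user-supplied aortic region mask
form the calcium mask. Maximal connected components under 26-connectivity
(configurable to 6-connectivity) are discrete lesions; lesions smaller
than 4 voxels are discarded. The minimum-size rule is applied per 3-D
lesion by default — consistent with 3-D volume scoring — with a
per-axial-slice variant available for workflows that follow the 2-D
convention.

The **length-adjusted calcium score** is

    LACS = V / L    [mm³/cm]

where V is the total filtered lesion volume (voxel count × voxel volume)
and L the arc length of the center lumen line between the same anatomical
landmarks. Length adjustment makes scores comparable across arterial
segments of different lengths. Because the contrast threshold sits far
above 130 HU, partial-volume shells of each plaque fall below it and the
contrast LACS is systematically lower than the noncontrast LACS; a
multiplicative correction factor (default 1.9) converts a contrast LACS
to its noncontrast equivalent. The factor is re-estimable from paired
data as the least-squares slope of noncontrast on contrast scores,
through the origin by default: a calcium-free artery must map to a zero
corrected score. (The free-intercept fit is available; with typical
score ranges the two slopes differ little.)

The classical Agatston score is included as a comparator: per axial
slice, each in-plane 8-connected lesion of area ≥ 1 mm² contributes
area × w, with w = 1/2/3/4 for maximum density 130–199 / 200–299 /
300–399 / ≥ 400 HU. No slice-thickness renormalization to 3 mm is
applied — scores from thin-slice protocols are therefore not directly
comparable to coronary reference ranges, which is acceptable for its
comparator role here. Risk bins: 0, (0, 100], (100, 400], > 400.

## Agreement statistics

Paired score series (contrast vs noncontrast, two observers, two slice
thicknesses) are compared with:

* **ICC**, single rating, two-way model, from ANOVA mean squares.
  Consistency ICC(3,1) is the default; absolute-agreement ICC(2,1) is
  implemented alongside, since published reliability reports often do not
  say which was used. 95% confidence bounds use the standard
  F-distribution construction; identical columns return exactly
  (1.0, 1.0, 1.0), and zero between-subject variance is an explicit
  error. Reliability labels: poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 <
  excellent (lower-inclusive bins).
* **Bland–Altman**: mean difference ± 1.96 × sample SD of differences,
  with the per-pair means/differences returned for plotting.
* **Paired rank test**: Wilcoxon signed-rank by default (all comparisons
  here are paired); Mann–Whitney U offered as a variant. Exact p-values
  at small n, two-sided. All-zero differences raise an explicit
  degenerate-test error. No multiple-testing adjustment is applied.

## The synthetic phantom

`lacs.phantom` fabricates paired contrast/noncontrast volumes of a
straight-axis abdominal aorta: uniform soft-tissue background (30 HU), a
2 mm wall (60 HU) around a 9 mm-radius lumen, and non-overlapping
ellipsoidal wall plaques (≥ 130 HU by definition, default ~800 HU with
30 HU texture). Compartments are painted by voxel-center inclusion in the
order background → wall → lumen → plaques, then blurred with an isotropic
Gaussian (FWHM 1.4 mm by default) as a partial-volume/blooming surrogate,
then degraded with additive Gaussian noise (10 HU). The contrast blood
pool is N(350, 50) HU — so μ + 3σ lands near the ~500 HU thresholds
typical of arterial-phase abdominal CT — and the noncontrast pool is
N(40, 10) HU. Each pair shares every stochastic field; only the blood-pool
attenuation differs, so score gaps within a pair are attributable to the
threshold alone.

Each spec is rendered at each requested reconstruction (0.75 mm and
2.0 mm z-spacing by default) on its own grid, with exact per-
reconstruction ground truth recorded before blur: per-plaque voxel
counts and volumes, and the exact centerline polyline with its arc
length. The default grid is 128×128 in-plane at 0.7 mm with a 60 mm
z-extent — a deliberately compact segment; LACS is length-normalized, so
segment length does not bias the score scale.

What the phantom does **not** model: anatomy (organs, bowel gas,
vertebrae), scanner physics (kVp/dose, PSF anisotropy beyond the single
Gaussian, streak/quantum noise, the higher noise of thin-slice
reconstructions), curved or tapering aortas by default (a polyline axis
is supported), and observer variability. Passing tests demonstrate the
correctness of the computational pipeline and the direction of the
contrast/noncontrast and slice-thickness effects, not clinical accuracy
on patient data; in particular the phantom-derived correction factor
(~1.15 under default blur) is smaller than factors reported from
patients, where blooming, motion and heterogeneous plaque densities are
stronger.

## Numerical choices

* Voxel-center convention throughout: index i sits at origin + i·spacing;
  ROI, plaque and lumen membership are decided by voxel-center inclusion
  with boundaries included. Sample SD (n−1) everywhere an SD is taken.
* Threshold comparison is ≥ (inclusive). A consequence worth knowing: on
  a noiseless phantom whose lumen is constant at exactly the computed
  threshold, the lumen itself is segmented; real ROI statistics always
  have σ > 0, which places the threshold strictly above the bulk of the
  blood pool.
* Thick-slice resampling (`mean_binning`) assigns each native slice to
  the half-open output interval [k·Δz, (k+1)·Δz) measured from the first
  native slice center and averages; it refuses to upsample. `linear`
  interpolates slice profiles instead.
* Centerlines from masks are per-slice lumen centroids ordered by z —
  adequate for a near-vertical aorta, not a general skeletonization.
  Slices without lumen voxels are skipped and the polyline bridges the
  gap.
* Contrast-pipeline false positives: Gaussian blur correlates lumen
  texture, so rare supra-threshold clusters inside the blood pool can
  survive the 4-voxel rule. On a plaque-free default phantom this floor
  is < 5 mm³, two orders of magnitude below typical plaque loads.
* Population phantoms (`random_phantom_spec`) draw 1–3 large
  (2.5–4.5 mm semi-axes) and 2–6 small (0.7–1.0 mm) wall plaques with a
  4 mm minimum surface separation, keeping lesions distinct under
  26-connectivity even after blur. Small plaques sit at the resolution
  limit of the 2.0 mm reconstruction, which drives the thick-slice
  lesion-count loss while the large plaques carry the volume.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; the same spec reproduces bit-identical
  volumes.

## Known limitations

ICC confidence bounds for the absolute-agreement definition use the
Satterthwaite approximation and can differ in the third decimal from
other implementations' rounding. DICOM support covers axial
single-series directories with rescale tags; orientation is taken on
trust rather than resampled from the image orientation patient matrix.
The Agatston comparator is not calibrated against any vendor
workstation.
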