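# Methods

## The measurement model

The pipeline treats an OCTA acquisition as two co-registered voxel grids —
decorrelation `D(z, y, x)` and structural reflectance `R(z, y, x)`, both on
[0, 1] — plus four segmented surfaces given as depth maps in µm from the
volume top: ILM, IPL, the RPE reference surface, and the RPE-Bruch
membrane complex.  Segmentation itself is out of scope; surfaces are
inputs.

**Slabs.**  An en-face image is the mean (optionally max) of the voxels
between two surface-relative boundaries, with half-open inclusion
(`inner ≤ z·pitch < outer`): a voxel exactly on the outer boundary is
excluded.  The canonical boundaries are:

| slab                      | inner        | outer        | channel      |
|---------------------------|--------------|--------------|--------------|
| choroid capillary default | RPE-Bruch+31 | RPE-Bruch+59 | decorrelation|
| choriocapillaris (10 µm)  | RPE-Bruch+31 | RPE-Bruch+40 | decorrelation|
| superficial plexus        | ILM+3        | IPL+15       | decorrelation|
| deep plexus               | IPL+15       | IPL+70       | decorrelation|
| avascular outer retina    | IPL+70       | RPE-ref+30   | decorrelation|
| RPE structural (~28 µm)   | RPE-ref−14   | RPE-ref+14   | reflectance  |

The RPE structural slab's boundaries are our reading of "~28 µm at the
level of the RPE": symmetric ±14 µm around the RPE reference surface.
The RPE reference and RPE-Bruch segmentations are modeled as independent
surfaces (no fixed offset is assumed between them).

**Flow-void cutoff.**  The avascular outer retina contains no vasculature,
so its decorrelation is pure noise floor.  Each eye's cutoff is the
arithmetic mean of its outer-retina slab pixels; choroidal pixels strictly
below the cutoff are flow void.  Strict `<` makes the behavior at
equality testable.  By default, artifact pixels are excluded from the
cutoff average (configurable): projection artifacts inflate the
outer-retina signal and would otherwise bias the threshold upward.

**Artifact masks.**  Both artifact classes are detected by a global
histogram threshold — the iterative-intermeans (isodata) fixed point
`t = (mean below t + mean above t)/2`, evaluated on a 256-bin histogram
that always spans [0, 1] regardless of input bit depth (bit-depth-stable
dialect; the algorithm is pluggable).  The bright class of the superficial
OCTA image is the projection mask; the dark class of the RPE structural
image is the shadow mask; their union is excluded from every denominator.
No morphological dilation is applied by default (a 1-px dilation is
available).  A constant input image means "no artifacts of that class";
pipelines pass `allow_blank` to map it to an empty mask rather than an
error.

**Modified ETDRS grid.**  Central subfield of 1 mm diameter plus four
parafoveal quadrants of the 1–2.5-mm annulus (the text's modified grid,
not the standard 3-mm parafovea), split along the two 45° diagonals;
pixels exactly on a diagonal go to the clockwise-next quadrant
(deterministic tie-break).  The grid centers on the raster center (scans
are fovea-centered; the center is configurable).  Nasal/temporal follow
laterality with the image held in one fundus orientation: nasal is the
left half-annulus for a right eye (OD), mirrored for OS.  Subfield
percentages use the subfield's own artifact-free area as denominator.  A
fully artifacted subfield is reported *undefined*, never 0.

**EZ colocalization.**  EZ-intact status is an input annotation per scan
line (manual B-scan grading in practice; the generator supplies truth).
The ten lines are rows 17, 47, …, 287 (1-based) of a 304-line raster; for
other raster heights the rows map proportionally, `round(n·k/304)`.
Within deep-capillary nonperfusion, artifact-free pixels on these lines
are partitioned by EZ status; each class's flow-void percentage is
void length / total length, with lengths as pixel counts (equivalent to
summed transverse run lengths).  Artifact pixels are excluded from both
classes symmetrically — the same exclusion rule as the subfield
percentages.

**Cohort statistics.**  Center-involved DME is CSF thickness strictly
exceeding 299.52 µm (the device-scale equivalent of the classic 250-µm
cutoff); eyes with SSI ≤ 60 are excluded (strict gate).  Normality is
screened with a one-sample KS test against a normal with the sample's
mean and SD; note that with estimated parameters this test is
conservative (p-values are biased upward), which matches its screening
role.  Group comparisons use one-way ANOVA with Bonferroni-corrected
pairwise Student's t tests (Welch optional), correlation uses Pearson's r.
Bonferroni multiplies each pairwise p by the number of pairs, capped at 1.

## The synthetic generator

The generator emulates the *statistical* structure the analysis consumes,
not optics (no speckle, no PSF).  Everything derives from a single seed
via spawned child generators, so identical parameters give bit-identical
eyes.

* **Choriocapillaris**: lobule mosaic from a jittered hexagonal lattice of
  centers at the geometric-mean lobule spacing (default diameter range
  60–300 µm), bright cores (~0.57) grading to dim seams (~0.30).  Voids
  are the sub-threshold set of a smoothed Gaussian random field; the
  threshold is an exact order statistic, so the void fraction of the
  artifact-free area equals the requested `true_void_fraction` to within
  one pixel.  Void pixels get decorrelation ~0.018 ± 0.008 (clipped to
  ≤ 0.04), well below the noise floor.  The field's correlation length is
  ~2 px at 304 (≈ 20 µm), giving void dots of a few tens of µm — the
  small end of the lobule scale.
* **Outer retina**: per-voxel truncated-normal noise, mean 0.06, SD 0.02 —
  the quantity the cutoff rule estimates.
* **Superficial vessels**: a random branching tree of 3-px-wide strokes
  grown segment by segment from the raster center until the bright-pixel
  fraction reaches `vessel_density` (default 0.15); every vessel pixel is
  8-connected to the root.
* **Artifacts** are applied *after* ground truth, so recovery tests can
  quantify the benefit of removal: under vessel footprints, decorrelation
  of everything posterior to the superficial slab gains
  0.35 × vessel intensity; under each hyperreflective lesion disk
  (default 3 disks, radius 70–150 µm, written bright into the inner
  retina), both channels from the outer retina down are multiplied by
  0.10 — darkening the RPE slab (detectable shadow) and pushing normal
  choriocapillaris below the cutoff (a genuine false-void hazard when
  removal is off).
* **Deep nonperfusion and EZ disruption**: sub-threshold sets of one
  smooth field, so disrupted regions are nested inside nonperfusion.
  Defaults (`deep_nonperfusion_fraction` 0.35, `ez_disruption_fraction`
  0.5) model the heavily ischemic eyes of an EZ substudy — eyes selected
  for a foveal avascular zone outline destroyed over half its
  circumference; cohort generation scales both down for milder grades.
  Beneath disrupted EZ the local void fraction is enriched ×3 (capped at
  0.5), with the fraction outside lowered so the field-wide fraction
  still equals `true_void_fraction` exactly.
* **Cohort covariates**: the grade → void-fraction map is
  {no DR 2.0%, mild 2.5%, moderate 3.5%, severe 4.5%, PDR 5.5%} plus a
  small per-eye jitter (SD 0.2 pp) — the ordering and rough effect sizes
  of severity trends; published per-grade moments parameterize CSF
  thickness, SSI (resampled until > 60), age, HbA1c, and duration.
  Visual acuity is linked to the eye's *realized* ground-truth CSF void
  percentage: `logMAR VA = −0.05 + 0.03 · (CSF void %) + N(0, 0.10)`.
  With the noise at 0 the VA–void correlation is exactly 1 by
  construction.  DME flags derive from the thickness cutoff.

What passing tests on this generator do **not** show: robustness to
segmentation error, speckle, defocus, motion artifact, or pathology the
scene model lacks (e.g., RPE atrophy).  They do show that the measurement
chain — thresholding, artifact exclusion, grid accounting, line
accounting, statistics — is correct and unbiased on data with known truth.

## Numerical choices and problem sizes

* Mean projection is the default (max is available per slab spec): mean
  preserves the reduced-decorrelation contrast the cutoff rule assumes.
* Depth convention: µm increase posteriorly from the volume top; voxel
  `iz` sits at `iz × axial_pitch`.  Pixel indexing is 0-based internally;
  only reports use the device's 1-based line numbering.
* Raster default 304 × 304 over 3 × 3 mm (pitch ≈ 9.87 µm/px), axial
  pitch 3 µm; both configurable.
* Ties/degenerate inputs: pixels equal to the cutoff are not void; a
  constant image has no isodata threshold; a subfield or EZ class with an
  empty denominator is undefined, not zero; empty cohorts after the SSI
  gate abort the run.
* Simulation-heavy checks (recovery, uniformity, cohort Monte Carlo) run
  at a reduced problem size — raster 160, axial pitch 6 µm — and the EZ
  Monte Carlo at raster 304, axial pitch 6 µm; these sizes are the
  package's reduced-size defaults for batch simulation.  All scientific
  parameters (effect sizes, noise levels, fractions) are identical at
  every size.

## Known limitations

* The isodata "global threshold" is one published reading of generic
  global auto-thresholding; the exact histogram dialect of other tools
  may differ by a bin or two (the implementation is cross-checked against
  an independent isodata implementation to within one bin).
* Whether artifact pixels belong in the outer-retina cutoff average is an
  interpretation; excluded by default, includable by flag.
* The per-subfield artifact-free denominator (rather than a whole-image
  denominator) is likewise an interpretation, chosen because it keeps
  each subfield's percentage self-contained.
* EZ grading and ischemic-maculopathy grading are consumed as
  annotations; automating them is out of scope.
* The generator's covariate effect sizes are plausible defaults, not
  fitted values; only their signs and orderings are anchored to published
  observations.
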