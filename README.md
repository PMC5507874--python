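# ccflowvoid

Quantification of **flow-void (non-flow) areas in the choriocapillaris** on
OCT angiography (OCTA), for researchers studying inner-choroidal perfusion
in diabetic retinopathy (DR) and related macular disease.

OCTA maps blood flow as a decorrelation signal between repeated B-scans.
In the thin choriocapillaris slab just posterior to the RPE-Bruch membrane
complex, regions whose decorrelation falls below an eye-specific noise
floor are read as disrupted inner-choroidal flow.  This package implements
that measurement pipeline end to end:

1. **Slab extraction** — en-face projections between segmented surfaces:
   superficial plexus (ILM+3 → IPL+15 µm), deep plexus (IPL+15 → IPL+70),
   avascular outer retina (IPL+70 → RPE-ref+30), two inner-choroidal slabs
   (RPE-Bruch+31 → +59 and the 10-µm slab RPE-Bruch+31 → +40), and a
   structural RPE slab (~28 µm).
2. **Per-eye cutoff** — the threshold `θ = mean(D_outer-retina)`: the
   avascular outer retina carries no vessels, so its mean decorrelation is
   the eye's noise floor.  Flow void is `D < θ` (strictly below).
3. **Artifact exclusion** — isodata (iterative-intermeans) global
   thresholding marks projection artifacts (bright class of the
   superficial OCTA image) and shadow artifacts (dark class of the RPE
   structural image); their union leaves both numerator and denominator of
   every percentage.
4. **Modified ETDRS grid** — per subfield S (1-mm central subfield + four
   parafoveal quadrants of the 1–2.5-mm annulus):
   `void % = 100 · |void ∧ ¬artifact ∧ S| / |¬artifact ∧ S|`.
5. **EZ colocalization** — along the ten standard scan lines (rows
   17, 47, …, 287 of 304), within deep-capillary nonperfusion, flow-void
   percentages are compared between spans with intact vs disrupted
   photoreceptor ellipsoid zone (EZ).
6. **Cohort statistics** — center-involved DME classification (CSF
   thickness > 299.52 µm), scan-quality gate (SSI > 60), KS normality
   screening, Student's t, one-way ANOVA with Bonferroni-corrected pairs,
   Pearson correlation.

Because clinical OCTA volumes are rarely shareable, a **seeded synthetic
generator** reproduces the statistical structure the pipeline consumes —
lobular choriocapillaris mosaic with planted voids, a branching
superficial vessel tree, shadow-casting lesions, a low-signal outer
retina, deep nonperfusion with colocalized EZ disruption, and eye-level
covariates — with exact ground truth for every stage.

## Worked example

```python
import ccflowvoid as cc

params = cc.SyntheticEyeParams(dr_grade="severe_NPDR",
                               grid_size=160, axial_pitch_um=6.0, seed=7)
eye = cc.generate_eye(params)
report = cc.run_eye(eye)

print("cutoff:", round(report["cutoff"]["value"], 4))
sub = report["slabs"]["choriocapillaris_10um"]["subfields"]
for name in ("CSF", "superior", "nasal", "temporal", "inferior"):
    print(f"{name:9s} void %: {sub[name]['void_pct']:.2f}")
print("truth CSF void %:", round(eye.truth_csf_void_pct, 2))
print("EZ disrupted vs intact: %.2f%% vs %.2f%%"
      % (report["ez"]["pct_disrupted"], report["ez"]["pct_intact"]))
```

prints

```
cutoff: 0.06
CSF       void %: 3.06
superior  void %: 3.17
nasal     void %: 4.12
temporal  void %: 3.77
inferior  void %: 5.14
truth CSF void %: 3.06
EZ disrupted vs intact: 15.19% vs 2.35%
```

The recovered cutoff is the generator's outer-retina noise floor (0.06);
the measured central-subfield void percentage matches the eye's planted
ground truth to two decimals; and the flow-void percentage beneath
disrupted EZ far exceeds that beneath intact EZ, as this severe-NPDR eye
was generated with a ×3 void enrichment under EZ-disrupted regions.

A CLI wraps the same stages:

```
ccflowvoid simulate --grade PDR --seed 7 --out eye_dir/
ccflowvoid run-eye --volume-dir eye_dir/ --ez-annotation eye_dir/ez_annotation.csv --out report.json
ccflowvoid run-cohort --n-per-grade 25 --seed 0 --out cohort.json
```

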