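# Methods

## Image model and segmentation

A single spheroid in an ultra-low-attachment round-bottom well projects as
one dark, roughly elliptical body near the centre of a phase-contrast
field, often with a thin bright rim and small dark debris nearby. The
pipeline in `imaging.segment_spheroid` is:

1. **Threshold.** The image is lightly smoothed (Gaussian, σ = 0.6 px) and
   cut at the Yen maximum-correlation threshold. Yen's criterion for a
   normalised histogram p and cut t is
   TC(t) = −ln(G₁G₂) + 2·ln(P(1−P)), with P the cumulative probability and
   G₁, G₂ the within-class sums of squared bin probabilities;
   `yen_threshold` maximises it exhaustively over all cuts (verified
   bin-for-bin against an independent brute-force scan and against
   scikit-image). The returned value is the midpoint between the argmax
   bin and the next occupied bin, so it falls strictly between separated
   classes.
2. **Cut refinement.** On nearly discrete histograms the raw Yen cut can
   land at an extreme micro-class (the bright rim, a handful of
   quantisation-tail pixels) or inside a tightly quantised cluster.
   Because a centred single spheroid must occupy between 0.4% and 50% of
   the frame and be separated from the background by ≥ 3 pooled
   within-class SDs, `refine_threshold` re-derives the cut on a shrinking
   intensity interval until those conditions hold (or the interval is
   exhausted). This is the package's substitute for the unpublished
   artefact-cleaning internals of the original macro; the Yen operator
   itself remains the pure histogram criterion.
3. **Cleaning.** Objects below 0.5% of the image area are removed, holes
   are filled, and of the surviving objects the largest is kept (exact
   ties broken by centroid proximity to the image centre, matching the
   centred-culture geometry). Area is measured after hole filling.
4. **Empty-well rule.** A well is reported empty when no object of ≥ 1% of
   the image area survives, or when the final cut separates classes by
   < 3 pooled within-class SDs (a flat noise field offers no real object;
   without this guard, thresholded noise can percolate into large spurious
   components).
5. **Measurements.** Area in µm² (pixel count × scale²), equivalent-sphere
   radius r = √(S/π) and volume V = (4/3)πr³, and Feret diameters from the
   convex hull of boundary-pixel corners (max: largest vertex distance;
   min: rotating-calipers minimal width). Aspect ratios above 1.5 set a
   warning flag — the equivalent-sphere estimate degrades beyond that
   ellipticity. The volume path uses area only; Feret-based ellipsoid
   volumes are noticeably more threshold-sensitive.

The µm-per-pixel calibration is a mandatory parameter; all physical
outputs scale with it (area ∝ k², volume ∝ k³, Feret ∝ k).

## Synthetic image fixtures

`fixtures.generate_spheroid_image` renders: mid-gray background (180), dark
elliptical interior (60), ~2 px rim (235), optional debris discs of 2–6 px
radius at the body intensity placed ≥ 4 px clear of the rim, additive
Gaussian noise, quantised to 8-bit. The frame is sized so the body fills at
most ~40% of pixels. Ground truth (π·a·b, aspect a/b) is carried on the
truth record. The generator emulates contrast polarity, debris separation
and empty wells — not optics: no PSF, no illumination gradients, no texture
inside the body. A green segmentation suite therefore establishes correct
geometry recovery under the stated contrast model, not performance on real
micrographs. Measured fidelity on the stated world (200 seeded images,
diameters 150–800 px, noise SD ≤ 10, ≤ 20 debris specks): median relative
area error ≈ 0.004%, well under the 5% macro-vs-manual benchmark.

## Plate simulation

`fixtures.simulate_plate` lays a run out on a 96-well map (6 replicate rows
× 9 half-log concentrations 0.03–300 µM; vehicle controls in column 10,
25%-DMSO kill controls in column 11, a cell-free media row). Raw reader
units are `500 + 4500·viability/100`, perturbed multiplicatively by
`1 + (CV/100)·z` — variability on plates is reported as CV, so noise is
proportional to signal. At CV 0 readings sit exactly on the truth curve.

The monophasic default is logIC50 = 0.5 (3.16 µM), Hill −1, top 100,
bottom 0, CV 10%, 6 replicates. The biphasic default traces the observed
neural-stem-cell shape: a very sharp first transition (logIC50₁ = −1.0,
nH₁ = −3) complete by ~0.3 µM, a ~50% shoulder to ~3 µM (frac = 0.5), then
a moderate second decline (logIC50₂ = 1.5, nH₂ = −1) reaching ~5% at
300 µM. A unit first slope cannot complete its transition within one
decade and would erase the printed plateau, hence the steep nH₁. Camera
and reader noise levels are free parameters of the generator, not
calibrated claims about any instrument.

In this parameterisation Y → top as X → +∞ for positive slopes, so
decreasing viability curves carry negative Hill slopes; "hill = 1" in
protocol descriptions is read as slope magnitude.

## QC statistics

Z-factor, signal window and CV are the standard definitions (the SW
equation follows the NCATS Assay Guidance Manual form,
SW = (|µ_h − µ_l| − 3(σ_h + σ_l))/σ_h, since the source renders it only as
an image). Z with media-only controls and Z′ with DMSO controls are the
same operation applied to different role selections. Pass criteria:
Z > 0.4, SW > 2, CV < 20% (strict inequalities; CV = 20% fails).

**Outliers.** The published ROUT method couples robust nonlinear
regression with FDR-controlled outlier tests. Plate-uniformity data is a
location-only problem, so a reduced variant is used: residuals from the
median, robust scale from the 68.27th percentile of |residuals| (×n/(n−1)),
two-sided t p-values, Benjamini–Hochberg step at rate Q (default 1%).
Constant data flags nothing.

**Normality.** `dagostino_k2` is the D'Agostino–Pearson omnibus test
(scipy's `normaltest`), K² = Z²_skew + Z²_kurt ~ χ²(2); it requires n ≥ 20.
Type-I error measured at 5.2% over 1000 plates of 66.

**Power.** `detection_power` treats the published design as a two-sample
one-tailed t-test, n per group, control mean 100 with SD = CV and treated
mean 100 − drop with SD scaled to its mean; power from the noncentral t
with pooled-SD noncentrality ncp = drop/(σ_pooled·√(2/n)), df = 2n − 2.
This reading gives 76.7% (CV 15) and 98.9% (CV 9) for a 20% drop at n = 6,
α = 0.05, agreeing with a 2×10⁵-replicate Monte-Carlo t-test oracle to
three decimals. (An equal-SD normal-approximation reading reproduces the
commonly quoted 74%/99% pair almost exactly; the noncentral-t computation
is kept because it is the exact answer for the stated design.) A
one-sample variant is available via `design="one-sample"`.

**Normalisation.** Two anchorings of the % scale: *validation* (highest
reading → 100%, cell-free media mean → 0%) and *cytotoxicity* (vehicle
control mean → 100%, 25%-DMSO positive control mean → 0%). The map is
linear and never clipped. Fitted logIC50 and Hill are invariant under any
affine change of the raw scale (top/bottom absorb it).

## Dose-response fitting

Unweighted least squares (`scipy.optimize.curve_fit`), replicates entering
as individual points to preserve residual df. Initialisation: plateaus
from the extreme-concentration means, logIC50 at the concentration nearest
mid-range (4PL) or the 25th/75th percentile log-concentrations (biphasic,
frac = 0.5), |hill| = 1 with the sign taken from the data's orientation.
Slope magnitudes are bounded to [0.1, 10]; biphasic sites are ordered
logIC50₁ < logIC50₂ after fitting (swapping frac → 1 − frac). Vehicle
(concentration-0) wells are normalisation anchors only and never enter the
log-concentration fit. Standard errors come from the residual-scaled
Jacobian covariance; 95% CIs use t(df) quantiles. Non-convergence is
reported on the result (`converged=False`), never silently repaired.
A `pin_bottom` option fixes the bottom plateau (e.g. at 0 on the
normalised scale); by default the bottom is free.

**Combination across runs.** *pooled*: one fit on the concatenated points.
*geometric_mean*: mean per-run logIC50 with a t CI on k − 1 df (equals the
geometric mean of the IC50s on the linear scale); on homogeneous runs its
CI tends to be slightly wider than pooling's. *shared_ftest*: a global fit
with per-run plateaus and slopes but one common logIC50, compared to the
fully separate fits by F = ((SS_sh − SS_sep)/Δdf)/(SS_sep/df_sep); p <
0.05 sets a "runs differ" flag. Under the CV-noise simulation the test is
mildly conservative (empirical type-I ≈ 3.5% at nominal 5% over 600 runs)
because the unweighted residuals are heteroscedastic; this is a property
of the stated noise world, not of the test statistic.

Monte-Carlo characterisation on the stated world (CV 10%, 6 × 9 design,
200 seeds): 4PL logIC50 recovered within ±0.15 log units in ~99% of runs
with 95.0% CI coverage; biphasic logIC50₁/logIC50₂/frac within their
bands in ~94–96%; on monophasic data the nested F-test retains the 4PL in
92% of runs.

## Numerical and interface choices

- All randomness flows from explicit integer seeds (`numpy` Generator);
  identical seeds give bit-identical images, plates and output files.
- CSV outputs carry `#`-prefixed headers with the package version and a
  digest of the scientific configuration (output paths excluded from the
  digest so runs into different directories remain comparable).
- Well addresses are letter-row + 1-based column (A1..H12); sample wells
  must carry a condition; duplicate or unknown wells are hard errors with
  the offending address and line number.
- The CLI (`simulate`, `measure`, `qc`, `fit`) is a thin layer over the
  library; `simulate → measure → qc → fit` composes into a full screen on
  synthetic data.

## Known limitations

- The image fixtures' hard-edged, three-level world is adversarial for
  entropy thresholding in ways real micrographs are not (discrete
  histogram spikes); the bracketed cut refinement addresses it, but very
  low noise (SD ≈ 0.3–0.6) combined with many debris specks can still
  occasionally defeat segmentation (~0.3% of fixtures), which then reports
  an empty well rather than a wrong area.
- Feret diameters use pixel-corner hulls; on very small objects (< ~10 px
  across) the ±0.5 px corner convention dominates the estimate.
- The biphasic fitter assumes both transitions are bracketed by the
  concentration range; truths with sites outside 0.03–300 µM are not
  identifiable from the default design.
- No spatial plate effects (edge evaporation, gradients) are modelled, and
  no minimum-significance-ratio analysis is provided.
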