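# Methods

`ssbmd` implements, at desk scale, a single-energy radiographic
bone-densitometry pipeline: a calibrated physics model of a digital
radiography (DR) system, an inverse solver that recovers a morphological
model of the forearm from one radiograph, automated forearm ROI placement,
aBMD/T-score computation, and the statistical machinery used to validate
such a device against a reference standard.  Everything runs on synthetic
inputs generated by the package itself; no external data is read.

## The morphological model

The imaged object is described by two co-registered 2-D maps:

* **total thickness** `T(x)` — posteroanterior tissue thickness along each
  ray, in cm;
* **alloy** `a(x)` — the proportion of soft tissue along the same ray,
  dimensionless in [0, 1].

Projected **bone thickness** is `B = T·(1 − a)` and, multiplied by the
assumed volumetric density of bone `ρ_bone` (default 1.85 g/cm³, always
recorded in outputs), its ROI mean becomes areal bone mineral density
(aBMD, g/cm²).  Background pixels (`T = 0`) carry `a = 1` by convention.
Grids are row-major, rectangles half-open, distal = smaller column index,
and laterality is handled by mirroring across the long image axis.

Note the alloy orientation: published group means for this kind of device
(total thickness ≈ 4.6 cm, alloy ≈ 0.78, bone ≈ 1.03 cm at the
ultra-distal radius) are mutually consistent only with `B = T·(1 − a)`,
i.e. alloy as the *soft*-tissue proportion.  That convention is used
throughout.

## Forward physics

Per pixel, the expected energy-integrating detector signal is

    primary = gain · mAs · Σ_E w(E) · E · exp(−μ_soft(E)·T·a − μ_bone(E)·T·(1−a))

with a filtered-Kramers 60 kVp tungsten spectrum `w(E)` on a 1 keV grid
(10–60 keV, 2.5 mm Al filtration), and mass attenuation tables for
water-equivalent soft tissue and cortical bone, log-log interpolated
between 10 keV-spaced anchors.  Scatter is a thickness-dependent
scatter-to-primary ratio applied to a spatially smoothed primary field:

    scatter(x) = s0 · (1 − exp(−T(x)/τ)) · [G_w ∗ primary](x)

with defaults `s0 = 0.4`, `τ = 3 cm`, Gaussian kernel width `w = 1 cm`.
The smoothing uses zero-padded (truncated-kernel) convolution; that
discrete operator is exactly self-adjoint, which the analytic gradients of
the inversion rely on.  Detected counts are Poisson around
primary + scatter.  The default gain puts the unattenuated signal at
~1.2·10⁵ counts/pixel at 2 mAs, emulating a low-noise flat-panel detector.

Deliberate simplifications: no Monte-Carlo transport, no detector
blur/MTF, no beam-hardening correction beyond the polychromatic sum, no
magnification (SID is metadata only).

Calibration fits `gain`, `s0` and `τ` by least squares on per-band mean
intensities of step-wedge exposures; on noiseless self-generated exposures
it is an exact fixed point, and it recovers a perturbed gain to well under
1%.

## The inverse problem and its identifiability

At a single beam energy, attenuation alone cannot separate thickness from
composition: for slabs, `primary_equivalent_pair` constructs (T₂, a₂) with
exactly the primary transmission of (T₁, a₁) in closed form.  Two further
facts shaped the solver design:

1. **Scatter breaks the slab degeneracy.**  The scatter field depends on
   T through the scatter-to-primary ratio and on the image structure
   through the smoothing kernel, so the two members of a primary-equivalent
   pair produce measurably different images (≫ the Poisson noise at
   2 mAs), and an unconstrained inversion with a handful of parameters
   (uniform slab) recovers the true pair from either side of the
   degeneracy curve.

2. **Scatter does not identify free per-pixel maps.**  With one
   measurement per pixel and two unknown maps, any smooth thickness
   perturbation admits a compensating alloy field that reproduces the
   image exactly; this was verified empirically during development
   (image residuals at machine precision with grossly different aBMD).
   Plausible solutions must therefore be anchored anatomically — soft
   tissue surrounds two narrow elongated bones, and the skin surface does
   not bulge over them.

The solver therefore proceeds in the order a device pipeline would:

1. **Water-equivalent pass** — solve per-pixel thickness with `a ≡ 1` by
   damped Newton iteration against the full forward model.
2. **Bone-shadow detection** — bone only ever *raises* water-equivalent
   thickness, in narrow lateral bands.  Per column (pooled ±2 columns), a
   quadratic is fitted to squared thickness — the lateral profile of an
   elliptical limb cross-section is exactly quadratic in T² — with
   asymmetric rejection of positive residuals (scale taken from the
   negative side).  Pixels whose excess over this background exceeds
   0.15 cm, eroded away from the silhouette fringe and then dilated by
   2 px, form the working bone shadow.  This classical detector stands in
   for learned tissue-bone segmentation, which is out of scope.
3. **Anatomical prior** — inside the shadow the total-thickness prior is
   the background profile (smooth skin assumption) and the initial bone
   thickness follows from the water-equivalent excess scaled by
   `μ_soft/(μ_bone − μ_soft)` at the tissue-hardened mean energy.
4. **Joint refinement** — bounded quasi-Newton (L-BFGS-B) over
   coarse-to-fine bilinear control grids (default node spacings 4 px then
   1 px = pixel resolution), minimising the Poisson-weighted chi-square
   plus a quadratic tether of thickness to the prior (σ = 0.25 cm) and a
   roughness penalty (λ = 10⁻², scaled by pixels-per-node) that
   tie-breaks near-equivalent morphologies.  Gradients of the full
   forward model (spectral attenuation, scatter, priors) are analytic;
   alloy is free only inside the bone shadow, with bounds
   T ∈ [0, 12] cm and a ∈ [0, 1].

Convergence is declared at reduced chi-square ≤ 1.05 — "agreement within
the statistical errors of the system" has no published numerical value, so
this threshold is the package's choice and is recorded in every result.
Reduced chi-square is chi-square per pixel: at pixel resolution the number
of effective free parameters is governed by the priors and a
degrees-of-freedom subtraction would be arbitrary.  The iteration trace
stores the best chi-square after each accepted step and is non-increasing
by construction.

`anatomical_prior=False` disables steps 1–3 and the tether, leaving the
pure simulate–compare–refine scheme over free maps; with a near-uniform
(2×2-node) parameterisation this is the configuration used for the slab
degeneracy studies.

## ROI placement and scoring

Bone is segmented from the estimated maps by thresholding `B` at 0.05 cm
(Otsu optional); the two largest components with substantial mean bone
thickness are retained (shallow fringe artefacts rejected).  The radius is
the more lateral component given laterality; its most distal pixel (ties
toward the smaller row) is the styloid keypoint.  The ultra-distal (UD)
band runs 1.0–2.5 cm proximal of the styloid; the distal-third (DT) band
is 2.0 cm wide centred `arm_length/3` proximal of it (29 cm default arm
length when unmeasured).  These extents are conventions registered under
`forearm-default-v1`, not published facts.  aBMD is the ROI-rectangle
mean of `B` restricted to the bone mask, times `ρ_bone`; the T-score is
`(aBMD − μ)/σ` against a sex- and region-specific reference range, with
osteoporosis classified at T ≤ −2.5 (boundary inclusive; a 10⁻⁹ guard
absorbs floating-point rounding of the division).

Reference ranges are synthetic: `build_reference_ranges` scores a
"healthy young" phantom population (narrow bone jitter centred ~10–18%
above nominal, males slightly larger) and the frozen output
(`synthetic-v1`) ships with the package.  No manufacturer reference data
is bundled, so T-scores are meaningful only within this synthetic world.

## Synthetic phantoms

Forearm phantoms are a smooth elliptical soft-tissue dome (summit ~4.6 cm
at the wrist to ~7.6 cm proximally) containing two capsule bones with
elliptical-chord projected thickness, a distal flare on the radius, and
Gaussian-smoothed edges (σ = 0.18 cm).  Per-seed jitters on overall
thickness (±8%), bone calibre (±8%) and bone mineral fraction (±40%)
spread the UD ROI-mean bone thickness over roughly 0.6–1.5 cm, spanning
the published cohort interval 1.03 ± 0.17 cm.  Generation is a pure
function of (params, seed).  What these phantoms do *not* emulate:
cortical/trabecular structure, marrow, fat/muscle contrast, positioning
variation, pathology, or any real projection anatomy — so passing tests
demonstrate correctness of the measurement chain under the model's own
physics, not clinical performance.

## Synthetic cohort and statistics

The per-arm cohort generator draws a latent skeletal status per
participant (loaded on age, weight and sex), correlates arms (ρ = 0.92)
and regions (ρ = 0.90), and sets reference aBMD to the published marginal
moments (UD 0.35 ± 0.09, DT 0.66 ± 0.12 g/cm²; age 70.92 ± 9.03 y;
female fraction 0.5603; risk-factor prevalences from the published
categorical table).  Device outputs are affine in the latent truth plus
Gaussian noise whose level is set by the residual-SD target
(0.042 g/cm² by default): the latent device–reference correlation is
`r = sqrt(1 − (0.042/σ_region)²)`, which is also the closed-form oracle
the tests check.  A residual target exceeding the regional SD is a
configuration error (negative implied signal variance).  Reference ranges
for the cohort are placed so that per-arm osteoporosis prevalence is 0.27.

The statistics layer provides: exclusion accounting over a participant
roster (the default roster reproduces the validation scenario's
arithmetic: 261 enrolled → 257 retained, 492 reference forearms, 490
analysis wrists, 1.53%/6.13% excluded); forward–backward stepwise OLS
selection by AIC over linear+quadratic terms starting from the full base
model (tie tolerance 10⁻⁶, fixed term order); percentile bootstrap CIs
(defaults B = 5000, 99%); rank-statistic AUC with DeLong
structural-components variance for CIs; Wilson intervals for
sensitivity/specificity; Bland–Altman bias and 1.96·SD limits; and
grouped summary tables (Welch t, independent-samples rank-sum — the
correct statistic for two independent cohorts, though such protocols
sometimes name a signed-rank test — and direction-adjusted per-variable
AUC with the orientation flagged; categorical two-proportion chi-square
with continuity correction).  Greedy stepwise search is not guaranteed to
attain the exhaustive-subset AIC minimum on strongly collinear designs
(e.g. raw quadratics of correlated device outputs); on structured data it
does, and that is the regime the acceptance check exercises.

`run_validation` chains generator → stepwise fits → predicted T-scores →
logistic risk model with ROC/DeLong → Bland–Altman → fracture-history
sensitivity/specificity → summary tables.  On the default synthetic
cohort this lands in the qualitative vicinity of the headline values such
a device reports (adjusted R² ≈ 0.80/0.88, risk AUC ≈ 0.95, residual SD
≈ 0.042) — reported, not asserted, since those published numbers come
from clinical data that the generator only emulates in its marginals.

## Problem sizes and numerics

The acquisition default is a 24 × 12 cm field at 0.05 cm pitch
(240 × 480 px).  Validation runs and tests use the same field at 0.15 cm
pitch (80 × 160 px), which resolves the radius across ~11 pixels and
keeps one inversion at ~2–3 s; a 50-arm end-to-end run takes ~2 minutes.
Noiseless recovery at this scale: ROI-mean aBMD within 2% of truth on 30
seeded phantoms (regression slope ~1.00, R² > 0.999); with Poisson noise
at 2 mAs the automated chain classifies T ≤ −2.5 in full agreement with
ground truth away from the threshold.  Degenerate inputs are defensive
errors throughout (empty masks, single-class outcomes, rank-deficient
designs, degenerate wedges, infeasible noise targets).

## Known limitations

* Identifiability of the full-resolution inversion rests on the
  anatomical prior; the scatter model alone constrains only coarse
  parameterisations.  Objects violating the smooth-skin or
  bones-inside-soft-tissue assumptions will be mis-decomposed.
* The bone-shadow detector assumes a convex, roughly elliptical limb
  cross-section; it replaces learned segmentation and has no robustness
  claim on real radiographs.
* Material tables are 6-anchor approximations; spectra are analytic
  Kramers forms, not measured.
* T-scores are relative to synthetic reference ranges and are not
  comparable to any clinical densitometer's output.
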