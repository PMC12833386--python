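# Methods

## Problem and scope

`spinedvc` reconstructs internal lumbar-spine mechanics from pairs of 3-D
scan volumes acquired in two postures (neutral supine and extended lordosis).
The measurement chain is:

1. subset-based digital volume correlation (DVC) between the two volumes,
   yielding a displacement field on a regular node grid;
2. removal of the common rigid-body motion between the scans;
3. Green–Lagrange strain mapping and per-disc summaries;
4. per-vertebra translations, segmental anterolisthesis, and screening of
   every kinematic quantity against the protocol's precision estimates;
5. landmark-based clinical spine metrics (disc heights, Cobb angles, sagittal
   alignment, Pfirrmann consensus);
6. a statistical layer relating the biomechanical outcomes to the clinical
   metrics (collinearity screen, backward elimination, residual diagnostics,
   familywise correction, inter-rater ICC).

Because participant imaging data cannot be redistributed, the package ships a
phantom module that generates every input synthetically with analytic ground
truth, and all quantitative claims are validated against those oracles.

## Axis and sign conventions

All volumes are indexed `(x, y, z)` = (anterior–posterior, +posterior;
cranial–caudal, +cranial; lateral, +right), isotropic spacing in mm.
Landmark geometry lives in the sagittal `(x, y)` plane.  With these axes a
positive sacral slope (anterior rim of the S1 superior endplate inferior to
the posterior rim) makes the anterior→posterior endplate direction *rise*,
and lordotic wedging rotates each more cranial endplate clockwise.  Segmental
lordosis is the Cobb angle `angle(inferior endplate of the inferior
vertebra) − angle(superior endplate of the superior vertebra)`, positive
lordotic; lumbar lordosis is the same construction between the S1 and L1
superior endplates and equals the sum of the segmental angles for planar
geometry.  Anterolisthesis is reported anterior-positive: since Vx is
posterior-positive, `A = (−Vx_sup) − (−Vx_inf)`.  The raw Vx difference has
the opposite sign; the anterior-positive form is used so that a larger
positive number means a larger forward slip.

## Phantoms

**Texture.** Images are analytic sums of Gaussian blobs (default density
0.0115 blobs/voxel, widths 0.8–1.6 voxels).  A deformed volume is the
continuous texture sampled at inverse-mapped voxel centres, so phantom pairs
carry *no* interpolation error and correlation error is attributable to the
engine alone.  Blob evaluation bins points into spatial cells and culls
far-away blobs, keeping cost proportional to local blob density.

**Deformations.** `phi(x) = c + t + R(I + A)(x − c) + q(x − c)` with rigid
translation `t`, rotation `R` about the volume centre, small affine gradient
`A`, and an optional quadratic displacement `q`.  Displacement, deformation
gradient and Green–Lagrange strain are evaluated in closed form; the inverse
is exact for rigid+affine and Newton-iterated (tolerance 1e−10) when the
quadratic term is present.  Invertibility is checked via `det F > 0` at the
domain corners.

**Spine geometry.** Vertebral bodies are blocks with parallel endplates;
discs are wedged slabs.  Prescribing exact anterior/posterior heights `a, p`
measured orthogonal to the mid-disc (bisector) plane requires the wedge
angle `phi = 2 asin((a − p) / (2 d))` for vertebral depth `d` — the `sin`
form (not `tan`) makes the landmark-measured heights match the prescription
exactly, because the rim landmarks sit at fixed arc positions on the tilted
endplate lines.  Default geometry: 10 mm central disc height, wedge angles
2–10° growing caudally, 25 mm vertebral bodies, 40° sacral slope — plausible
adult values.  The phantom records every prescribed metric in its truth
object.

**Cohorts.** Outcome = linear predictor + Gaussian noise over the same
column vocabulary the clinical models use (age, gender, BMI, average disc
height, anterior:posterior height ratio, degeneration bins with
non-degenerated as reference, segmental lordosis, lumbar height, sacral
angle), with plausible marginals (age U(20, 70), BMI N(23.8, 2.6²), ratio
U(1, 2), …).  The default planted model uses two effects of equal
standardised size (`ap_ratio` 16.8, `age` −0.34) with noise SD 4.5, which
puts the full-model adjusted R² near 0.7 at n = 15 — the regime the
statistical layer is meant to operate in.  Equal standardised effects are
used because recovery of *both* planted predictors is the property of
interest; a lopsided split makes one predictor undetectable at any noise
level consistent with that R².

## Correlation engine

Schedule 48–32–24–16 voxel subsets, passes 1-1-2-2, 50 % overlap (node
spacing = subset × (1 − overlap); 8 voxels = 4.64 mm at the final stage for
0.58 mm voxels), minimum valid voxel fraction 0.5.  Coarse stages use
zero-mean Hann-windowed circular FFT cross-correlation with the peak search
limited to ±subset/4; the final stage uses zero-normalised cross-correlation
(ZNCC) over a bounded ±3 voxel search.  Ties on the correlation peak go to
the lowest total displacement (bias toward null motion).  Per-pass sub-voxel
estimation is the separable three-point Gaussian peak fit (log-parabola),
falling back to a plain parabola when a correlation sample is non-positive.
An exact integer match (ZNCC ≈ 1) skips refinement, since any fitted offset
would be jitter from the finite-window autocorrelation's asymmetry.

Two corrector refinements beyond the plain peak fit proved necessary to
reach the strain-precision floor the pipeline targets:

* **Warped seeding.** In the final-stage passes the deformed search region
  is spline-resampled at the fractional part of the seed displacement plus
  the seed field's local displacement gradient about the subset centre.
  This puts the residual peak near zero offset (where the three-point fit is
  unbiased, removing pixel locking) and undoes intra-subset rotation or
  stretch that would otherwise broaden and bias the peak.
* **Gauss–Newton sub-voxel refinement.** After the final pass, each node's
  translation is refined by up to 3 Lucas–Kanade iterations minimising the
  sum of squared intensity differences over the whole subset (cubic-spline
  resampling, in-window central-difference gradients, stop at 1e−3 voxel).
  Pooling the intensity residual over all subset voxels rather than a
  handful of correlation samples roughly halves the error (measured: rms
  0.018 → 0.009 voxel on rigid-pair phantoms).  Exact matches are fixed
  points, so integer-shift recovery stays exact.

Validity: a node is invalid when its subset holds less than 50 % mask
foreground, is textureless (zero variance), or its shifted search window
leaves the volume.  Invalid nodes carry no displacement and are excluded
from every aggregate; seed interpolation fills them from the nearest valid
node.

Measured performance on 64³ speckle phantoms at 0.58 mm: integer shifts
exact to 1e−14 voxel; 0.3-voxel uniform shift to 0.003 voxel; affine warps
(gradient ≤ 0.03) to 0.013 voxel RMS ≈ 0.007 mm.

## Rigid-body removal

Translation = mean displacement over valid nodes; rotation = orthogonal
polar factor of the least-squares linear map from reference to deformed node
positions about the valid-node centroid (at least 4 non-coplanar nodes
required).  Removal composes the field's mapping with the *inverse* rigid
transform, `u'(x) = T⁻¹(x + u(x)) − x`, which is exact for finite rotation
angles; naive subtraction of the rigid displacement is only first-order
correct.  Whether removal happens before or after strain mapping is
immaterial for the strains themselves — E is invariant under left-composed
rotations — and the package asserts this to 1e−6.

## Strain mapping

Displacement gradient by central differences on the node grid (one-sided at
grid boundaries), node spacing in mm as step; a node's gradient is valid
only if the full stencil neighbourhood is valid.  `E = (G + Gᵀ + GᵀG)/2`;
principal strains are eigenvalues in descending order; maximum shear is
`(ε1 − ε3)/2` (tensorial; the engineering convention `ε1 − ε3` is an
option).  Per-disc summaries take nodes whose subset centre voxel lies in
the disc mask: mean = unweighted average, peak = signed value of largest
magnitude, both in percent.  Levels with no qualifying node raise an
"unresolvable" error rather than emitting a summary.

Zero-strain floor: on repeat-scan phantom pairs (0.8° rotation, ~1 mm
translation, no deformation — the repositioning one expects between
successive supine scans without deliberate posture change) the full pipeline
leaves per-disc mean principal and shear strains at 0.11–0.16 %, inside the
protocol's cited 0.18 % strain precision.  Gradient noise scales as
`√2 σ_u / (2 h)` with node spacing `h`, and the mean principal strains carry
a positive bias from eigenvalue ordering even for zero-mean tensor noise —
this is why the corrector refinements above, not just averaging, were needed
to reach the floor.

## Kinematics and precision screening

Vertebral translation = mask-averaged valid-node displacement; Vtot is the
norm *of the averaged components* (not the average of node norms), the
convention under which quadrature propagation of the per-axis precisions
(0.165, 0.129, 0.138 mm) reproduces the 0.251 mm total-translation
precision.  Worst-case linear propagation of the Vx precision through the
anterolisthesis difference gives 0.330 mm.  A measured quantity is
"resolved" only if |mean| or range reaches 10× (inclusive) the relevant
precision; everything else is flagged below-precision and excluded from
modelling.

## Clinical metrics

Measurements operate on explicit landmark coordinates, mirroring manual
caliper placement in a viewer.  The mid-disc plane is the angle bisector of
the two bounding endplate lines (the natural reading of "orthogonal to the
mid-disc plane" when the endplates are not parallel).  Average disc height
is the mean of the anterior, central and posterior site heights.  Pfirrmann
consensus is the rounded average of the three ratings (half away from zero;
with three integer raters the mean only hits thirds, so the rule matters
only for even rater counts), binned 1–2 → ND, 3 → D, 4–5 → SD.

## Statistics

* VIF screen: iteratively remove the worst predictor while any
  `VIF = 1/(1 − R²_j) ≥ 10`; perfect collinearity is ledgered as infinite
  VIF.  Implemented over statsmodels' `variance_inflation_factor`.
* Backward elimination: OLS with intercept; drop the largest partial
  `p ≥ p_out` (default 0.10, the common default where the original analysis
  software does not print it) and refit until all retained `p < p_out`.
  Intercept-only outcomes are reported and flagged rather than erroring.
* Diagnostics: Shapiro–Wilk residual normality and Breusch–Pagan
  homoscedasticity at α = 0.05, automating the visual checks; violating
  models are marked excluded.  Constant residuals (noise-free fits) pass.
* Hommel familywise correction via statsmodels `multipletests`; the test
  suite verifies it against a brute-force closed-testing oracle (Simes tests
  over all intersection hypotheses) and the dominance ordering
  Hommel ≤ Hochberg ≤ Holm.
* ICC(2,1) — two-way random effects, absolute agreement, single measurement,
  with 95 % CI — via pingouin, cross-checked against a direct ANOVA
  mean-squares oracle.  Identical raters short-circuit to 1; zero
  between-subject variance is flagged degenerate.

## Problem sizes and numerical choices

The shipped configurations use 64³ correlation phantoms, 1–2 level spine
phantoms at 1 mm spacing (the coarsest subset must fit the lateral extent,
hence the 10 mm phantom margin), cohorts of n = 15, 200-replicate
Monte-Carlo batteries, and 1000-draw closed-testing comparisons; a full
pipeline run takes well under a minute on one core.  Newton inversion
tolerance 1e−10; ZNCC tie tolerance 1e−12; Gauss–Newton refinement capped at
3 iterations, 1e−3 voxel stopping, updates larger than 1 voxel rejected;
symmetric-tensor tolerance 1e−6.

## What the phantoms do and do not show

The phantoms have exact, band-limited, noise-free texture, geometrically
simple anatomy, and globally smooth deformations.  Passing tests therefore
demonstrate the correctness of the estimators and their noise floor under
ideal imaging — they do not bound errors from MRI noise, bias fields,
through-plane interpolation of anisotropic acquisitions, segmentation error,
or tissue boundaries moving relative to the texture, all of which affect
in-vivo data.  Known limitations: translations are resolved in the global
axis frame rather than vertebra-local frames; whole-disc summaries only (no
annulus regions); the DVC engine is single-threaded pure NumPy/SciPy.
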