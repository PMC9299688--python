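# Methods

## The cortical model

A CT density profile sampled along the inward surface normal of a vertebra is
modelled as a piecewise function of depth `x` (mm):

    rho(x) = y_bg                          x < x0        (soft tissue)
             y_c                           x0 <= x < x1  (cortical plateau)
             linear y_c -> y_t             x1 <= x < x2  (endocortical slope)
             y_t                           x >= x2       (cancellous interior)

with `x0 <= x1 <= x2`, `y_c > y_bg`, `y_c > y_t >= 0`.  The scanner observes
`rho` convolved with a Gaussian point-spread function of standard deviation
`sigma` along the profile.  The convolution has a closed form: error-function
terms for the step at `x0` and the standard ramp-times-Gaussian
antiderivative `Psi(u) = u Phi(u/sigma) + sigma phi(u/sigma)` for the slope;
the implementation is verified against adaptive-quadrature convolution to
better than 1e-6 of the cortical density.

Derived metrics follow the cortical-bone-mapping conventions: cortical
thickness Ct.Th = (x1+x2)/2 − x0 runs from the periosteal edge to the
*midpoint* of the endocortical transition (cortex and endocortex overlap, as
they do histologically); endocortical thickness Ec.Th = x2 − x1; Ct.BMD =
y_c; Cn.BMD = y_t; and cortical mass surface density
CMSD = 0.1 · Ct.Th · Ct.BMD (mg/cm²).  Because Gaussian blur conserves
integrals, the cortical excess mass above the two-level background equals
(y_c − y_t) · Ct.Th exactly — the physical reason CMSD is the most robust of
the five metrics.

## Fitting

Each vertex profile is fitted by bounded nonlinear least squares in the
parameterization (x0, w1=x1−x0, w2=x2−x1, y_bg, y_c, y_t) with analytic
Jacobians.  Initialization is heuristic (edges from smoothed gradients,
plateaus from tail medians), with one multi-start retry on poor convergence.
Two interchangeable engines exist: scipy `least_squares` (trust-region
reflective; the per-profile reference) and a vectorized projected
Levenberg–Marquardt that fits hundreds of profiles sharing one sample grid
at ~2 ms/profile; the test suite cross-checks them.

Validity screens: convergence; Ct.Th in [0.05, 5] mm; densities in
[0, 2000] mg/cm³; cortical–cancellous contrast ≥ 50 mg/cm³; residual RMS ≤ 3×
the noise SD.  Invalid vertices are filled by surface smoothing downstream.

### Identifiability and the per-scan density constraint

Below the PSF width, thickness and density trade off along a nearly flat
ridge (a thinner, denser cortex blurs to almost the same profile).  A
Fisher-information analysis with the analytic Jacobian shows that for a
uniform 0.9 mm cortex at sigma = 1.0 mm and noise 25 mg/cm³, per-scan Ct.BMD
is estimable to no better than ±18% — by any unbiased estimator — from 500
vertices.  Real vertebrae are not uniform: thickness spans roughly
0.2–2 mm within one bone, and the thick regions anchor the density.  The
pipeline therefore constrains y_c per scan, analogous to the per-scan PSF
policy:

1. **Anchor selection.** Profiles in the top 15% by integrated cortical mass
   (area above the background/interior baseline — blur-invariant), with an
   absolute floor equivalent to a 1.2 mm cortex at 800 mg/cm³.
2. **Anchor fits.** Free-density fits with the endocortical width frozen
   (its freedom is what de-conditions the plateau; the resulting model
   mismatch is second order in Ec.Th/sigma).  Each anchor is weighted by the
   inverse variance of its linearized density SE.
3. **Longitudinal coupling.** Baseline and follow-up scans of one subject
   share anchors.  The baseline level is a weighted median of anchor
   densities; the density *change* is the log-ratio of weighted anchor means,
   which cancels the anchor-fit bias common to both time points.  A small
   parametric bootstrap (anchors re-simulated from their own fitted
   parameters, 4 replicates) removes the residual cross-talk bias that a
   thickness change induces in the estimated density change.
4. **Constrained pass.** All vertices are re-fitted with y_c fixed per scan;
   Ct.Th, Ec.Th, Cn.BMD and CMSD come from this pass.

At the study conditions this recovers subject-level percentage changes with
errors of roughly ±3 pp (Ct.Th), ±2 pp (Ct.BMD), ±1 pp (CMSD) and ±0.4 pp
(Cn.BMD) per subject, essentially unbiased.

At heavy noise (≥10% of the cortical density) the endocortical width is
unidentifiable per profile and its positivity bound rectifies noise into an
upward thickness bias; the recommended configuration there freezes the
transition width (`w2_max ≈ 0`), which leaves Ct.Th unaffected because it is
defined to the transition midpoint.

### The PSF policy

Jointly fitting sigma and a sub-resolution thickness per profile is
ill-posed, so sigma is fixed per scan — either known from the protocol (the
simulated cohorts) or estimated from the thickest, highest-contrast quartile
of profiles with sigma free (`estimate_global_sigma`).  The estimate is
trusted only when a majority of candidate profiles support a resolvable free
fit and the fitted sigmas agree (IQR ≤ 25% of the median); otherwise the
configured default is used with a warning.  For anisotropic scanner blur the
per-vertex effective width is `sqrt(sig_ip²(nx²+ny²) + sig_sl² nz²)`.

## Surface maps

Profiles are sampled every 0.2 mm from 4 mm outside to 8 mm inside the
surface (trilinear interpolation; out-of-volume samples missing), truncated
at half the chord length to the opposing surface so the far cortex cannot
contaminate the fit — the reason interior metrics are meaningless in
pedicles and processes.  Metric maps are smoothed with a Gaussian kernel
over geodesic (graph-distance) neighbourhoods (default FWHM 5 mm), which
removes noise and fills vertices whose fit failed; weights renormalize over
valid vertices only.  Cn.BMD and Ec.Th are reported for vertebral-body
vertices only.  Percentage-change maps floor the baseline per metric
(Ec.Th 0.02 mm, densities 10 mg/cm³, Ct.Th 0.05 mm, CMSD 1 mg/cm²) and flag,
rather than clamp, vertices below the floor.

## Registration and correspondence

Each subject mesh is registered to a canonical shape by ICP (two
point-to-point steps for global alignment, then point-to-plane refinement —
point-to-point alone leaves a residual misrotation on smooth shapes),
followed by an iterated thin-plate-spline warp driven by dense closest-point
projections (normal-directed targets keep the warp quasi-radial and avoid
tangential correspondence slip).  Canonical vertices then receive
(triangle, barycentric) coordinates on the warped subject surface; maps
transfer by barycentric interpolation, validity by conjunction, labels by
barycentric majority.  Phantom cohorts share topology, so registration can
be bypassed (`identity_correspondence`) to isolate downstream stages.
Tangential correspondence on a textureless surface is fundamentally
ambiguous; across randomized smooth deformations (≤ ~10% scale) the mean
absolute transfer error of a smooth field stays below 5% of its range.

## Group statistics

Per-subject global change per metric is the ratio of means over vertices
valid at *both* time points (pairing avoids selection asymmetry; the
ratio-of-means is stabler than the mean of per-vertex ratios, which the
per-vertex display maps use).  Group summaries: mean ± SD, two-tailed
one-sample t vs baseline, two-tailed Welch t between groups, one-way ANOVA
for baseline comparability.  Zero-variance groups short-circuit to exact
equality (p = 0 or 1).

Vertex-wise SPM uses permutation of the maximum statistic for family-wise
error control: sign flips for within-group change, label permutation between
groups, the observed labelling included in the null (exact under
exchangeability), exhaustive enumeration when feasible.  Non-significant
vertices render light gray; out-of-scope regions dark gray.  Permutation
correction was chosen over random-field theory because it is assumption-light
and its error rate is directly verifiable by Monte Carlo.

## The synthetic cohorts

The generator emulates the study inputs: three arms (n = 20/19/17), subject
baseline truths drawn from the trial's printed baseline distributions,
12-month percentage changes drawn per arm from the printed change
distributions and applied multiplicatively (CMSD changes are never drawn —
they follow from the Ct.Th and Ct.BMD draws), the same PSF at both time
points (same scanner), Mindways-style linear HU encoding, and additive
Gaussian density noise (SD 25 mg/cm³).

Per-vertex truth fields are spatially heterogeneous log-normals around the
subject mean — CV 0.45 for Ct.Th, 0.60 for Ec.Th, 0.06 for Ct.BMD, 0.12 for
Cn.BMD — reflecting the wide within-vertebra thickness spread seen in
validation imaging and histology (thin shell vs endplate rims).  The
periosteal edge jitters uniformly ±0.2 mm per vertex (mesh placement error).
Uniform-truth phantoms remain available but are the degenerate worst case
for density identifiability and are used only for stage-isolation tests.

3-D phantoms rasterize the layered model by analytic signed depth on a fine
grid (first-order signed distance of the implicit ellipsoid; exact for
spheres), soften the periosteal step across one fine cell (first-order cell
average, which makes the rendering converge quadratically), blur with the
anisotropic PSF, block-average to the scan grid, add noise and encode to HU.

What the generator does **not** emulate: beam hardening and calibration
drift, structured/correlated CT noise, cortical porosity gradients,
double-shell or indistinct cortices, true anatomical L1 geometry, and
segmentation errors beyond the normal-direction jitter.  Passing tests
therefore demonstrate correctness of the measurement machinery under the
stated imaging model, not robustness to every clinical artefact.

## Problem sizes and numerics

Recovery experiments use 500 vertices/subject (the acceptance script) or
120–150 (repetition tests); profiles have 61 samples.  The batch LM runs at
most 100 iterations with per-profile damping and treats a no-descent state
under heavy damping as bound-constrained convergence.  Degenerate inputs:
`x1 = x2` collapses to the classic two-step model everywhere, including the
closed form and Jacobians; flat or contrast-inverted profiles fail
initialization explicitly.

## Known limitations

* **Ec.Th at slice-thickness resolution.**  The ramp-vs-step signal is second
  order, ~(y_c−y_t)·w²/24·max|g″|: for a 0.09 mm transition under a 1.0 mm
  PSF it is ~0.06 mg/cm³ against 25 mg/cm³ noise, and the per-profile CRLB of
  the width exceeds 5 mm even for a 2 mm cortex.  Per-vertex Ec.Th estimates
  at these conditions are bound-rectified noise, and recovered group
  percentage changes are strongly shrunk toward zero.  In-plane PSFs of
  0.4–0.8 mm (thinner-slice or in-plane-dominated profiles) carry up to ~6×
  more width signal.
* The method cannot distinguish reduced mineralization from increased
  porosity, nor detect periosteal apposition, at clinical CT resolution.
* The density constraint assumes the cortical plateau density varies slowly
  across the scan relative to its anchors.
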