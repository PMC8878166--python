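# Methods

## Display calibration model

An OST-HMD renders each eye through a fixed default projection
`P_default ∈ ℝ^{3×4}` whose implied eye position only approximates the
wearer's. Rather than re-estimating a full 3D-to-2D projective calibration
(the classical single-point active alignment route), the calibration is
framed as a black-box 3D-to-3D alignment: the user aligns a tracked marker
(centroid `x_C` in the tracking-camera frame) with a virtual reticle shown at
a known position `x_E` in the eye/display frame, and confirms. Each
confirmation yields one correspondence `(x_C, x_E)`; the camera-to-eye offset
is modelled as rigid — a deliberate restriction that trades a little
expressiveness for stability, since per-user eye offsets are dominated by a
small translation and rotation — and estimated per eye by minimizing

    error = Σ_i ‖ R a_i + t − b_i ‖²

over proper rotations, with `a = {x_C}` and `b = {x_E}`. The closed form
centers both sets, factors the cross-covariance
`H = Σ_i (b_i − c_b)(a_i − c_a)ᵀ = U S Vᵀ`, and takes
`R = U · diag(1, 1, d) · Vᵀ` with `d = sign(det(U Vᵀ))`, `t = c_b − R c_a`.
The determinant factor matters: with noisy or near-planar data the
unconstrained orthogonal optimum is occasionally a reflection, and the
correction projects it back to the rotation group. The corrected projection
is `P = P_default · T` with `T` the homogeneous form of the offset, applied
independently per eye. Both eyes must calibrate successfully; a degenerate
eye aborts the whole calibration because a stereo pair with one corrected and
one uncorrected eye is perceptually worse than no correction.

A unique rigid solution needs at least three non-collinear correspondences;
the session default is ten, which in the underlying study balanced
calibration time against quality. Correspondences are equally weighted.
Residual diagnostics (per-pair and RMS, in mm) are always returned even
though they are not part of the calibration output proper: they are the only
online indicator of a poorly performed session.

Coordinate conventions: right-handed, camera looks down +z, image origin
top-left with u rightward and v downward, 3D in meters, reported errors in
millimeters; points are column vectors and transforms premultiply (so
`P_default · T` composes in matrix order). The default reticle layout places
five positions (four corners + center of the central two-thirds of the
43° × 29° display frustum) at each of two depths, 0.4 m and 0.6 m. The
workflow this emulates does not fix a layout; the two-depth design is chosen
because a single-depth (near-planar) set conditions the rigid fit badly —
the depth spread is what makes the z-axis of the offset observable. Whether
the two eyes see identical reticle positions is configurable; the default
uses the same set.

## Marker-object registration

Scene alignment uses a pre-constructed rigid configuration of four square
markers with known marker-to-object poses. The object pose in the camera
frame is resolved from any subset of ≥ 2 detected markers by expressing each
detected marker's four corner points once in the object frame and once in
the camera frame and solving the same stacked rigid-alignment problem.
Using corners rather than marker centers keeps the rotational component
observable from two markers. Pixel-level marker detection is out of scope;
detections enter as poses.

## Point-and-trace evaluation

Ground truth for a trial is a phantom: a closed scar-like contour plus 19
ordered target points, printed with four black 10 mm corner square-markers on
a 120 × 120 mm page. The user's marked-up sheet is digitized at 300 DPI
(1 px = 25.4/300 ≈ 0.0847 mm) and processed as:

1. **Scan registration** (3 DoF: rotation + translation). A coarse estimate
   comes either from the four corner-marker centroids (default) or from an
   exhaustive rotation sweep (±10° in 0.5° steps) with per-angle
   phase-correlation translation; it is refined by maximizing normalized
   cross-correlation between binarized, Gaussian-smoothed (σ = 2 px) images,
   downsampled 4× for speed, with Nelder-Mead. The refinement is kept only
   if it improves the intensity metric. Alignment quality is the mean
   distance between corresponding corner-marker centroids after alignment —
   the quantitative version of the visual overlap check — and > 2 mm raises
   a registration failure.
2. **Point extraction.** A morphological opening (radius ≈ 0.6 mm) erases
   thin strokes so dots touching the traced contour remain separable;
   surviving components are filtered by area and aspect against the expected
   1.5 mm dot, and each blob's boundary pixels are fit with an algebraic
   (Kåsa) least-squares circle. Circle centers convert to mm via the DPI.
3. **Matching.** Detected points are unordered, so correspondence to ground
   truth is established by minimum-total-distance assignment (Hungarian
   algorithm) and the pairs are then sequenced by the recorded task order —
   the order in which the user approached the targets, noted during the
   session precisely so that user points can be related to their ground
   truths.
4. **TRE.** Per-pair Euclidean distance in mm; mean μ, sample SD σ (n−1
   convention, the safer choice for the small per-trial samples), RMS TRE
   `= √(μ² + σ²)`. RMS ≥ mean always, with equality at zero spread.
5. **ASSD.** Both contours are rasterized as 1-px-wide curves on a shared
   grid and the symmetric sum of nearest-boundary distances is computed with
   exact Euclidean distance transforms; this equals the brute-force
   all-pairs nearest-distance average to floating point (property-tested).
   The user contour is recovered from the scan by removing corner markers
   and dot blobs and skeletonizing the remaining ink.
6. **FRE.** RMS distance over corresponding fiducial centroid pairs; it is
   deliberately sensitive to correspondence, not just to the point sets.

Percent improvement between two RMS errors is `100·(before − after)/before`,
rounded to the nearest integer for reporting, matching how such gains are
typically quoted.

## Synthetic data generator

The generator supplies every input the pipeline needs, so the whole package
is testable without downloads; its defaults encode the study conditions the
evaluation is meant to operate under.

* **Phantoms.** The contour is a radially perturbed closed curve
  `r(φ) = r₀ + Σ_{k=2..5} a_k cos(kφ + φ_k)` with per-variant base radius
  (28.5–34.5 mm) and seeded harmonic amplitudes (0.8–2.2 mm) — irregular and
  scar-like without being spiky. Targets sit on a jittered hexagonal lattice
  of 10 mm pitch inside the contour, kept ≥ 4 mm clear of the contour line so
  drawn dots stay separable from the trace, ordered in a serpentine task
  sequence. The nearest-neighbour spacing constraint is [7, 13] mm — the
  "roughly 1 cm apart" band read as nearest-neighbour spacing, since a
  max-over-all-pairs bound of 13 mm cannot hold for 19 points that are
  mutually ≥ 7 mm apart. Light-gray landmarks (two vessel-like polylines and
  an outer heart contour) are printed on every template as localization cues;
  being above the ink binarization threshold, they never enter the metrics.
  The five variants are mutually distinct (pairwise contour Hausdorff
  distance > 5 mm, tested).
* **Simulated trials.** User points are truth plus isotropic Gaussian
  placement error; the user contour is truth displaced along its normals by
  a smooth correlated Gaussian field (white noise smoothed along arc length
  with a 10 mm correlation length, rescaled to the target SD) — independent
  per-vertex noise produces jitter no human tracing shows and breaks
  skeletonization. Rendered scans apply a random rigid page perturbation
  (|θ| ≤ 3°, |shift| ≤ 5 mm per axis) to emulate imperfect sheet placement
  on the scanner and exercise the registration. All generators are pure
  functions of their seeds (byte-identical reruns, tested).
* **Per-paradigm noise defaults** are set analytically from the summary
  accuracy levels of the five paradigms: for a target pooled TRE mean `m`,
  the per-axis point SD is `m/√(π/2)` (mean of a 2D Rayleigh); for a target
  ASSD `a`, the contour displacement SD is `a/√(2/π)` (mean of a folded
  normal). The TRE calibration is exact in expectation; the realized ASSD
  runs ~10 % above the analytic value because the displaced curve is locally
  longer where it wiggles, which the folded-normal approximation ignores.
  Task and calibration times are truncated normals with the per-paradigm
  means/SDs (floors of 15 s and 30 s keep them positive); NASA-TLX subscales
  are truncated normals on [0, 100] whose per-paradigm means follow the
  qualitative workload ordering (direct overlay lowers mental demand and
  effort; adding calibration improves perceived performance at the cost of
  demand and effort). These draws exist to exercise the statistics pipeline,
  not to model human behavior — passing tests show the pipeline's
  correctness, not behavioral realism.
* **Simulated calibration sessions.** A marker perfectly aligned with a
  reticle at `x_E` sits at `T⁻¹ x_E` in the camera frame; observations add
  isotropic Gaussian noise (given in mm) and plausible per-confirmation
  timestamps, so session timing is exercised end to end.

Large simulated studies (hundreds of users) compute TRE/ASSD directly from
the simulated geometry rather than rendering every page: the raster
pipeline's contribution is ~0.01 mm TRE / ~0.03 mm ASSD (measured as the
zero-noise floor), two orders of magnitude below the smallest paradigm noise
level, and rendering every trial would dominate runtime for no information.
The rendered path is exercised by the noise-floor and registration-recovery
checks and by the CLI.

## Study statistics

Per metric: Shapiro–Wilk per group (constant groups are rejected rather than
given a meaningless p), a one-way ANOVA for a common mean, and all pairwise
two-sample comparisons with Bonferroni adjustment `p_adj = min(1, m·p)`
(m = 10 for five paradigms) at a 0.05 family-wise threshold. Pairwise tests
are Welch's t — the omnibus source names only "ANOVA" with Bonferroni, and
Welch is the robust default under unequal variances. Repeat trials are
averaged within user before group comparison to avoid pseudo-replication.
Because it is not stated whether the original analysis pooled per-point TRE
samples across users or compared per-user means, both aggregations are
exposed (`mode="pooled"` / `mode="per_user"`, the latter the default).
Under a simulated global null the realized family-wise error rate is ~4–5 %
(Bonferroni is slightly conservative), and a 2σ group separation at n = 30
is detected essentially always — both recomputed by the acceptance script.

Raw NASA-TLX is the unweighted mean of the six subscales; the weighted
(pairwise-comparison) variant is out of scope.

## Numerical choices and degenerate inputs

* Rigid solver: sources are degenerate when the second singular value of the
  centered source matrix falls below 1e-10 of the largest (scale-relative);
  a cross-covariance determinant within 1e-12 of zero is reported as
  degenerate rather than guessing a sign.
* Registration: the translation of a 2D rigid transform is origin-dependent;
  recovery accuracy is therefore assessed as displacement error at the page
  center, and transform parameters are stored about the pixel origin with
  helpers to convert.
* Circle fit: algebraic Kåsa fit on boundary pixels — deterministic, no
  iteration, adequate at 300 DPI where a dot spans ~35 px.
* ASSD rasterization rounds vertices to the nearest pixel center; at 300 DPI
  this bounds the discretization error near half a pixel (~0.04 mm).
* Single-pair TRE uses SD = 0 (the n−1 estimator is undefined), making
  RMS = mean, consistent with the RMS ≥ mean invariant.
* PNG round-trips snap near-integer DPI values (PNG stores pixels per meter,
  which quantizes 300 DPI to 299.9994).

## Known limitations

* The eye-offset model is rigid; scale or projective components of a real
  display miscalibration are absorbed into the residual, not corrected.
* Point extraction assumes dots and strokes near their nominal sizes
  (1.5 mm radius dots, ~0.5 mm strokes); heavily overlapping dots — possible
  under the largest paradigm noise at the 7 mm spacing floor — merge and
  raise a count mismatch rather than being split.
* The intensity registration assumes the ±10°/±5 mm perturbation envelope of
  a sheet on a scanner bed; arbitrary rotations are out of scope.
* Simulated users have no bias, learning, fatigue or spatial error
  structure; only summary-level agreement with the reference accuracy levels
  is attempted, and the per-user bias/variance split is unknowable from
  summary statistics.
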