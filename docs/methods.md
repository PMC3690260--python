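# Methods

`diamoco` estimates a 1D respiration signal from rotational C-arm CT
projections by tracking the diaphragm contour, and uses that signal to
compensate respiratory motion during filtered backprojection. This note
documents the model assumptions, the numerical choices, and what the
synthetic phantom does and does not emulate.

## Coordinate conventions

World coordinates are millimetres, right-handed, with z along the
superior-inferior (SI) axis, which is also the rotation axis; the isocenter
is the origin. The source at gantry angle θ sits at
(SOD·cosθ, SOD·sinθ, 0); the flat detector is perpendicular to the
source-isocenter line at distance SDD from the source. Detector pixels are
0-based with pixel-center convention; the row coordinate v grows toward
inferior (image convention), so a diaphragm dome is a *minimum* in v and its
parabola has a > 0. Defaults: SOD 800 mm, SDD 1200 mm (typical C-arm values;
exposed as parameters), detector 640×480 at 0.616 mm/px, 200 views at
1.0°/view over 4 s.

## Diaphragm tracking

The hemidiaphragm contour in a projection is modelled as a detector-space
parabola v = a·u² + b·u + c. Per frame:

1. **Region of interest.** Frame 0: a 250×55 px rectangle centered on the
   user seed (sizes stated for 640×480; they scale linearly with detector
   resolution). Later frames: a parabolic band of ±10.5 px around the
   previous model, limited to the 250 px u-range around the previous vertex.
2. **Edge detection.** Gaussian smoothing and Canny edges, hysteresis
   thresholds at 10%/30% of the ROI's maximum gradient magnitude. The
   smoothing scale defaults to σ = 1 px: the diaphragm silhouette is a
   one-sided edge (air-like lung above, tissue below, with a square-root
   intensity profile at the tangency), and the derivative-of-Gaussian
   localization of such an edge is biased toward the bright side by an
   amount that grows with σ (≈0.6 px at σ = 2 on the synthetic phantom,
   ≈0 at σ = 1). Larger σ is available in the configuration for noisy data.
3. **RANSAC.** 20 000 exact 3-point parabola fits; inliers are points within
   1 px vertical distance; the most-consensual model wins, ties broken by
   smaller mean inlier residual then sample index, followed by a
   least-squares refit on the inlier set (kept only if it does not lose
   consensus). Degenerate samples (repeated u) are discarded. All sampling
   is driven by one seed; reruns are bit-identical.
4. **Constraints.** A candidate is rejected when (i) its vertex moved more
   than max(2 × running mean |Δu*|, 3 px) horizontally — the 3 px floor
   prevents lock-up while the running mean is still small; (ii) the
   curvature parameter changed by more than 5 % relative to the previous
   frame; or (iii) outside a ±15° free-motion window around the
   anterior-posterior viewing direction, the vertex moved against the
   expected horizontal direction. The expected direction is inferred from
   the median drift of the first five frames and flips once the turning
   point has been passed.
5. **Fallback.** A rejected candidate is replaced by a dead-reckoned
   previous model: the parabola is translated horizontally by the median
   per-frame drift of recent accepted frames, then b and c are refit by
   trimmed least squares (a held fixed) around that prediction. If the refit
   strays more than 3 px from the prediction — the signature of an
   interfering contour crossing the band — the prediction itself is kept.
   This keeps the tracker on course while the contralateral hemidiaphragm
   contour crosses the tracked one near lateral views, and lets it re-lock
   as soon as an unconstrained candidate reappears.

The per-frame constraint thresholds assume a small angular increment
(~1°/view). At several degrees per view the per-frame motion and
deformation genuinely exceed them and tracking degrades gracefully but
measurably; the test suite's coarse smoke test asserts a correspondingly
looser bound.

## Motion-corrected triangulation

Two-view triangulation assumes a static scene; during breathing the
diaphragm top moves several millimetres between the two acquisition times,
which biases naive triangulation by roughly the inter-view displacement.
The pipeline therefore:

1. pairs each frame i with the frame k views away (default offset 90°,
   falling back to i−k near the end of the scan; frame i is always the
   reference, so the output point is attributed to frame i's time);
2. rectifies the pair onto a common image plane whose x-axis is the
   baseline (both rectified cameras share the rotation and averaged
   intrinsics), making epipolar lines horizontal;
3. replaces the partner's rectified vertical coordinate with the
   reference's (motion correction) — after rectification a static point has
   equal vertical coordinates, so any residual vertical disparity is
   attributed to SI motion;
4. triangulates with the iterative Linear-Eigen method: the homogeneous
   4×4 system is solved by the smallest right singular vector, then each
   view's two equations are reweighted by the inverse of the current depth
   and the solve repeated (≤10 iterations, 1e-10 mm movement tolerance).

Because all sources lie in the z = 0 plane, the rectified vertical axis is
exactly ±z for every pair of this trajectory: the rectified v depends on
the world z only, and the horizontal coordinates are independent of z.
Consequently, for *purely* SI displacement between the two acquisition
times the corrected pair is exactly consistent with the reference-time
point, and triangulation with exact correspondences recovers it to machine
precision. Real data break this exactness through tracking noise,
deformation, non-SI motion components, and the apex-on-contour assumption
(the silhouette's topmost point is a tangency point, not the projection of
the 3D apex; the synthetic domes are kept near-spherical so this bias stays
below ~0.5 px, and the triangulation-error study bypasses it entirely by
construction, feeding exact apex projections).

The respiration signal is r̂ᵢ = z_ref − zᵢ with z_ref taken at the first
frame (scan start; configurable — the reference phase is a free choice and
shifts the signal by a constant), optionally smoothed with a unit-sum
Gaussian kernel (default σ = 2 frames, reflected boundaries). For targets
that move less than the diaphragm, a dimensionless scale is fit as the
through-origin least-squares slope of target displacement against diaphragm
displacement (both relative to their first sample).

## Motion-compensated reconstruction

Standard short-scan FDK with per-view voxel shifting:

- **Filtering.** Cosine pre-weighting SDD/√(SDD² + a² + b²), Parker
  redundancy weights (a 200° scan is a short scan; for spans ≥ 360° the
  weights reduce to the uniform 1/2), then row-wise ramp filtering by
  zero-padded FFT convolution with the discrete band-limited kernel,
  evaluated at the detector sampling rescaled to the isocenter plane so the
  volume keeps the projections' attenuation units. Shepp-Logan is the
  default kernel: its sinc apodization suppresses the Gibbs ringing that
  the pure Ram-Lak ramp produces at high-contrast edges (measurably visible
  around the phantom's 5 mm lesions); Ram-Lak is available in the
  configuration. The discrete kernel's truncation leaves a ~0.1–0.3 %
  residual when filtering a constant (non-compact) row; compact projections
  are unaffected.
- **Backprojection.** Voxel-driven: each reference-grid voxel is moved to
  its position at the view's acquisition time, projected, the filtered
  projection is sampled bilinearly (contributions off the detector are
  dropped), and accumulated with the FDK distance weight and the angular
  step. With the constant model the view-time position is p + (0, 0, −r̂ᵢ):
  the anatomy at view i sits inferior of its reference position by r̂ᵢ, so
  the reconstruction is formed at the reference phase. A motion model of
  `None` takes the same code path with zero shift and is bitwise identical
  to plain FDK.
- **Linear lung model.** For lungs the motion amplitude decays with height:
  shift(z) = −m·(z_max − z) for z ≤ z_max and 0 above, with
  m = rᵢ/(z_max − z_dia,i), where z_dia,i is the diaphragm-top height at
  view i and z_max a user-chosen zero-motion height (e.g. the lung apex).
- Default grid 128³ at 2 mm (desk scale; 256³ at 1 mm for figures).

## Synthetic dynamic-thorax phantom

The simulator replaces an anthropomorphic phantom with an analytic scene:
ellipsoidal body, two lung cavities (carved by explicitly flagged negative
primitives), a heart with two 5 mm high-contrast lesions *inside the right
lung cavity* (so the moving heart boundary carries the full
soft-tissue/lung contrast, as a real cardiac silhouette does), and two
diaphragm domes modelled as upper-half ellipsoid caps whose apexes bulge
into the lung bases. Heart, lesions and domes translate rigidly along SI by
A·sin²(πt/T) (peak-to-peak A = 23 mm, period T = 4 s = scan duration, i.e.
one full cycle starting and ending at end-exhale); the rest of the scene is
static. Projections are exact line integrals from closed-form ray-ellipsoid
(and clip-plane) intersections; Poisson noise at a configurable fluence is
available but off by default so that tracking and triangulation tests are
deterministic.

Two phantom-design choices matter for interpretation:

- The domes are near-spherical caps (semi-axes 24×26×22 mm). A strongly
  oblate cap places its silhouette top up to ~3 px away from the projected
  3D apex under oblique perspective, which would dominate the tracking
  error budget with a bias that is a property of the *phantom geometry*,
  not of the tracker.
- Attenuations (1/mm): body 0.02, lungs 0.0002, heart 0.025, lesions 0.04,
  domes 0.05. Only relative contrast matters; all values are configuration.

What the phantom does *not* emulate: realistic organ shapes and texture,
hysteresis or non-rigid breathing (the lung tissue between diaphragm and
apex is static in the simulation), cardiac motion, scatter, beam hardening,
and detector noise unless requested. Passing tests therefore demonstrate
the pipeline's geometric and algorithmic correctness under its stated
assumptions — rigid SI motion, visible hemidiaphragm, parabola-like
contour — not clinical performance.

## Evaluation instruments

- **SSIM slice curves.** Gaussian-window SSIM (σ = 1.5, K₁ = 0.01,
  K₂ = 0.03, dynamic range = joint max − min of the cropped inputs,
  population covariance) per xy- or xz-slice, on the bounding box of the
  heart at the reference phase. The comparison baseline is the FDK
  reconstruction of a motion-free scan (not the voxelized phantom), so both
  volumes share the reconstruction's spectral characteristics. Identical
  inputs score exactly 1; a common positive rescaling leaves SSIM unchanged
  (a common offset does not — the luminance term is deliberately
  shift-sensitive).
- **Triangulation-error study.** For each (mode, offset) cell, every
  frame's exact apex projection is paired, triangulated, and compared with
  the true apex at the reference frame's time; mean/std of the 3D Euclidean
  and |z| errors are tabulated. With exact correspondences the
  rectified-corrected errors are at numerical precision for this geometry
  (see above), far below the published means, which the acceptance check
  treats as upper bounds.
- **Line profiles.** Bilinear samples along a segment; used to compare edge
  sharpness across reconstructions.

## Problem sizes

The test suite and the acceptance script run the full 200-view study at the
640×480 detector for tracking and triangulation, and 128³ @ 2 mm grids for
reconstruction; unit tests use 20–40-view scans on quarter-resolution
detectors and 24³–48³ grids. These sizes were chosen so a complete run
stays comfortable on a single CPU while keeping every full-scale claim
(sub-pixel tracking, exact static triangulation, SSIM orderings) tested at
the study's native geometry.

## Known limitations

- The apex-on-contour assumption biases the *tracked* signal amplitude
  under perspective; reconstructing the full diaphragm surface would remove
  it but is out of scope.
- Only the 1D special case of motion-compensated backprojection is
  implemented (constant or linearly height-scaled SI shift); general 3D
  vector fields are not.
- Pair selection near the end of the scan reuses the backward partner i−k,
  which keeps the effective offset but correlates consecutive outputs.
- The linear lung model needs a user-supplied zero-motion height and a
  calibration of the diaphragm-to-target scale; both are inputs, not
  estimates.
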