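# diamoco — diaphragm-driven respiratory motion compensation for C-arm CT

Cone-beam C-arm CT acquisitions take several seconds, so free breathing (or
residual motion under breath-hold) blurs thoracic reconstructions —
problematic for cardiac imaging and for planning bronchoscopic procedures
where sub-2 mm airways must stay visible. `diamoco` implements an
image-based remedy that needs no external hardware: the respiration signal
is estimated from the projection images themselves and fed back into the
reconstruction.

The pipeline, for a rotational scan with per-view projection matrices Pᵢ
and timestamps tᵢ:

1. **Diaphragm tracking.** The user seeds one hemidiaphragm apex; each
   frame's contour is found by Canny edge detection in a region of interest
   and a RANSAC fit of the detector-space parabola v = a·u² + b·u + c
   (20 000 three-point models, 1 px inlier rule), stabilized by
   plausibility constraints (limited horizontal motion, ≤5 % change of a,
   consistent motion direction away from the turning point). The vertex
   (−b/2a, c − b²/4a) seeds the next frame.
2. **Motion-corrected triangulation.** Each frame's vertex is paired with
   the frame ~90° away, the pair is rectified onto a common image plane
   (epipolar lines horizontal), the partner's vertical coordinate is set to
   the reference's — after rectification any vertical disparity of a
   corresponding point is attributable to superior-inferior (SI) motion —
   and the pair is triangulated with the iterative Linear-Eigen method.
   The 1D respiration signal is r̂ᵢ = z_ref − zᵢ, Gaussian-smoothed.
3. **Motion-compensated FDK.** Short-scan filtered backprojection (cosine
   and Parker weighting, ramp filter) in which every voxel is first shifted
   to its position at the view's acquisition time — a constant SI shift
   −r̂ᵢ for rigidly moving targets such as the heart, or a linear lung
   model whose shift decays from the diaphragm top to a zero-motion height
   z_max with slope m = rᵢ/(z_max − z_dia).

A synthetic dynamic-thorax simulator (analytic ellipsoid scene, sinusoidal
SI breathing, exact line-integral projections) generates test data with
known ground truth for every stage. See `docs/methods.md` for the model
details, assumptions and limitations.

## Worked example

Accuracy of the motion-corrected triangulation under the reference study
conditions — 200 views at 1.0°/view over 4 s (SOD 800 mm / SDD 1200 mm,
640×480 detector at 0.616 mm/px), diaphragm apex moving 23 mm peak-to-peak
in one sinusoidal breathing cycle, with exact apex projections as
correspondences:

```bash
$ diamoco evaluate triangulation --n-views 200 --offsets 90,30,10 --out table.csv
             method  offset_deg      mean_3d       std_3d       mean_z        std_z
rectified_corrected        90.0 1.908428e-13 1.105314e-13 3.179679e-14 2.661632e-14
rectified_corrected        30.0 2.837882e-13 2.188371e-13 3.479883e-14 2.616809e-14
rectified_corrected        10.0 6.800791e-13 5.929592e-13 5.121237e-14 6.051230e-14
           standard        90.0 7.470258e+00 3.825539e+00 7.281173e+00 3.684861e+00
           standard        30.0 4.508034e+00 1.907425e+00 3.660475e+00 1.334177e+00
           standard        10.0 2.433493e+00 1.654483e+00 1.066110e+00 4.479548e-01
```

Columns are mean/std of the 3D Euclidean and |z| errors in mm against the
true apex position at each reference frame's acquisition time. Standard
(unrectified, uncorrected) triangulation is wrong by millimetres — a
sizeable fraction of the 23 mm excursion, because the apex moves between
the two acquisition times. The rectified, motion-corrected variant is exact
to numerical precision here: for this circular trajectory the rectified
vertical axis aligns with the SI axis, so zeroing the vertical disparity
removes a pure SI displacement entirely. With real (tracked) vertices the
errors are set by tracking noise instead; sub-millimetre accuracy is the
practically relevant statement.

The full pipeline on synthetic data, end to end:

```bash
diamoco pipeline --config examples/pipeline.yaml --out run/
# stages: simulate -> track -> triangulate -> signal -> reconstruct -> evaluate
```

which writes projections (multi-page float32 TIFF + JSON geometry sidecar),
`track.csv`, `points3d.csv`, `signal.csv`, uncompensated and compensated
volumes (`.mha`), per-slice SSIM curves against a motion-free reference
reconstruction, and a manifest with the seed and per-stage hashes. On the
23 mm-motion phantom the compensated reconstruction raises the mean
heart-crop SSIM from ≈0.50 to ≈0.87 and restores the 5 mm heart lesions
that motion smears over 2 cm (see `tests/test_recon_quality.py` and
`tests/test_acceptance.py` for the exact checks).

## Package layout

| module | contents |
| --- | --- |
| `diamoco.geometry` | detector/trajectory types, projection matrices, rays |
| `diamoco.simulator` | analytic breathing-thorax phantom and forward projector |
| `diamoco.tracking` | ROIs, Canny edges, RANSAC parabola, constraints, tracker |
| `diamoco.triangulation` | rectification, motion correction, Linear-Eigen |
| `diamoco.resp_signal` | signal extraction, smoothing, linear scale calibration |
| `diamoco.reconstruction` | short-scan FDK with constant/linear voxel shifting |
| `diamoco.evaluation` | SSIM slice curves, line profiles, triangulation study |
| `diamoco.io` / `diamoco.cli` | readers/writers, pipeline runner, `diamoco` CLI |
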