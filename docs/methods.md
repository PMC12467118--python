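# Methods

## The registration problem

A CBCT soft-tissue isosurface covers the whole head; a structured-light
face scan covers one frontal or lateral view of the face plus everything
else the sensor happens to see — hair, neck, clothing, shoulders. Both are
metric (mm) but live in unrelated coordinate frames, and the geometric
overlap between them is only the facial skin, typically 15–25 % of the
scan's points. The goal is the rigid transform taking the scan's frame into
the CBCT's frame, accurate to a fraction of a millimetre over that shared
facial region.

## Stage 1 — pose normalization

Each surface is loaded into a virtual scene with a pinhole camera at the
origin looking along +z (y up; a face presented to the camera points along
−z). The cloud is first translated so its centroid sits at (0, 0, d) with
d = 300 mm. A landmark provider — a face-mesh detector adapter, a
landmark-JSON replay, or the synthetic oracle — maps a rendered view to
the seven canonical face-mesh landmarks (19 nose; 162/389 outer eye
corners; 234/454 facial width; 132/361 jaw), from which four pose
descriptors are computed:

* roll — arctangent of the eye-corner line slope;
* yaw and pitch — arctangent of the nose offset from the mean of the six
  lateral landmarks, over the nose protrusion depth z₁₉;
* position (x, y) — the nose pixel coordinates;
* size D — the 3D distance between the width landmarks, in pixel scale.

A proportional controller scales each error by the gain p (default 0.01;
0.005–0.05 all converge, with termination time ∝ 1/p) and the corrections
are assembled into a homogeneous rigid update R = Rz·Ry·Rx plus
translation, applied to the cloud; the loop terminates when the summed
absolute angular errors fall below 0.01 rad and the summed position/size
errors below 6 px, with a hard cap of 500 iterations. Since both
modalities are driven to the *same* target (angles zero, nose at the
principal point, D₀ = 0.45 × image width), their facial regions end up in
a shared canonical frame; the residual mismatch (a millimetre or two) is
exactly what ICP is good at removing.

Three geometric points deserve note:

* **Detector depth convention.** Dense face-mesh detectors report z as a
  relative depth on the same scale as x and y. The detector frame here
  fixes that convention precisely: z_i = (d̄_lateral − d_i)·f/d_i, the
  landmark's forward protrusion relative to the lateral-landmark plane in
  its local pixel scale. With this choice the yaw/pitch descriptors
  approximate the true head angles (slope ≈ 1), so every error component
  contracts by ≈ (1 − p) per iteration — the behavior the gain and
  thresholds were tuned around. An absolute-depth reading would shrink the
  slope by ~5× and proportionally slow the loop.
* **Rotation anchor.** Orientation corrections rotate the cloud about the
  detected nose position (back-projected to mm), not the cloud centroid.
  For a clutter-heavy scan the centroid sits ~15 cm below the face, and
  rotating there couples every angular correction into face translation,
  dragging the loop well past its iteration budget; anchoring at the nose
  decouples the components.
* **Framing step.** Before the proportional loop, one translation-only
  correction moves the nose to the target pixel and the face to the target
  size. Centroid centering alone can leave the face of a torso-heavy scan
  hundreds of pixels off-axis (or outside the frame entirely) — a state a
  real detector could not even process, and one the acquisition protocol
  is supposed to exclude. The step is the identity for well-framed inputs.

Sign conventions follow from the camera geometry: because the face points
toward the camera, the image-measured yaw is the mirror of the
camera-frame Ry angle (roll and pitch are not mirrored), and a
larger-than-target apparent size moves the cloud away from the camera
(+z). Both are handled where the update matrix is built; the controller
law itself is uniformly δ = −p·Δ.

## Stage 2 — ICP refinement and threshold search

Correspondences run scan→CBCT: each source point takes its nearest target
neighbour (KD-tree) and the pair enters K iff its distance is strictly
below the threshold. The point-to-plane objective Σ((p − Tq)·n_p)² is
minimized by a small-angle linearization to a 6×6 least-squares system
(minimum-norm for rank-deficient geometry, so unconstrained directions —
e.g. in-plane sliding on a planar target — receive zero motion), with the
rotation restored through the rotation-vector exponential. A
point-to-point variant (closed-form SVD/Kabsch solution) is available.
Target normals, when absent, are estimated by local PCA over k = 20
neighbours; for the squared point-to-plane residual the normal sign is
immaterial. The loop stops when the relative change of the
per-correspondence mean objective drops below 1e-6 (interpreted as
relative: the sum form jumps whenever |K| changes size) or after 30
iterations; the final transform is the composition of all per-iteration
increments with the initialization.

The correspondence threshold trades robustness (large gates admit wrong
pairs — hair, clothing, the wrong side of a fold) against sufficiency
(small gates starve the estimate). Empirically the fitness-versus-threshold
curve is unimodal: descending from 10 mm it rises to a plateau once the
clutter is gated out, then collapses to zero when the gate falls below the
residual initial misalignment plus the sampling scale. The search descends
10, 9, 8, … while fitness does not *significantly* decline — a decline
counts only beyond max(5 % relative, 0.02 absolute), because consecutive
pre-peak evaluations carry run-to-run noise that the literal
"stop at first decrease" rule mistakes for the peak — then probes ±0.5 mm
around the best coarse value and returns the fitness argmax, ties broken
toward lower inlier RMSE and then lower threshold. Every threshold's ICP
restarts from the same pose-normalized initialization, making evaluations
independent and the argmax well defined. The search needs at most 13 ICP
runs versus 20 for an exhaustive 0.5 mm sweep.

Both clouds are voxel-downsampled for ICP (one member-centroid
representative per occupied voxel; the voxel, 0.5–1.5 mm, is chosen by
bisection so the downsampled target holds 20k–80k points). Fitness and
inlier RMSE, during the search and in the final report, are computed on
the full-resolution clouds: a 0.5 mm inlier cutoff cannot discriminate at
1.5 mm sampling — at that density a slightly misaligned pose can even
score higher. Distinct thresholds frequently converge to the identical
transform, so metric evaluations are cached per resulting transform.

## Evaluation metrics

* fitness — inlier correspondences / source points, cutoff 0.5 mm,
  strict inequality (configurable);
* inlier RMSE — root mean square nearest-neighbour distance over inliers
  only; with zero inliers it is reported as a failure, never as 0;
* 95th-percentile and Hausdorff distance — directed source→target by
  default (symmetric by flag), optionally restricted to a sub-region mask;
* error field — per-point distance clamped to [0, 5] mm through the jet
  colormap (dark blue = 0, dark red ≥ cap), exportable as colored PLY.

## The synthetic fixture generator

The generator defines the conditions every end-to-end test runs under; it
emulates the acquisition geometry rather than human facial statistics.

* **Head** (stands in for the CBCT soft-tissue surface): a superellipsoid
  skull with nose ridge, brow, eye sockets, cheekbones, chin and jaw
  bulges as radial Gaussian displacement fields, quasi-uniformly sampled
  by Fibonacci directions (default 100k points, facial width guaranteed
  within the anthropometric 120–160 mm). Eight seeded low-frequency lobes
  (σ = 2 mm), kept off the face, individualize each seed.
* **Scan**: a single-viewpoint capture from 800 mm at azimuth 0/±30°
  simulated by spherical-flip hidden-point removal plus a 75° grazing-
  incidence cutoff (structured-light triangulation fails on steeply tilted
  surfaces — this is what removes the far cheek and nose ala in lateral
  views). Non-CBCT content mirrors what the sensor sees but X-ray soft
  tissue does not: a hair-like shell offset 10–26 mm over the non-face
  scalp and a torso/clothing slab below the chin, sized so the scan→head
  overlap fraction lands near 20 % — the low-fitness regime characteristic
  of this multimodal pairing. Isotropic Gaussian noise (default
  σ = 0.1 mm, below the ~0.2 mm triangulation accuracy of such sensors)
  and a seeded rigid offset (rotation ≤ 30°, translation ≤ 50 mm),
  recorded as ground truth, complete the capture. With clutter disabled
  the noiseless scan is an exact subset of the head surface.
* **Oracle landmark provider**: recovers the cloud's current rigid pose
  from anchor points on every detection (exact for rigid motion) and
  reports the tracked 3D landmark truth exactly as a detector would —
  pixel coordinates plus relative depth, with optional Gaussian pixel
  jitter keyed deterministically to the view. Like a model-based face-mesh
  detector it reports anatomically correct landmarks even where the local
  surface is occluded; unlike a real detector it does not require the
  landmarks inside the image frame and carries no cross-modality bias
  (rendered CBCT vs. photographic appearance).

What passing tests therefore do and do not show: they validate the
geometry, control loop, solvers, search logic and metric definitions under
realistic noise, overlap, clutter and view-direction conditions; they do
not measure detector-induced landmark error on real faces, non-rigid
expression changes between acquisitions, or human facial-shape diversity.
On real data the pose stage inherits whatever bias the landmark detector
has; the ICP stage is agnostic to it as long as the residual stays inside
the threshold-search range.

## Numerical choices and degenerate inputs

* Euler composition fixed as R = Rz·Ry·Rx; transform composition is the
  matrix product with the newest transform leftmost.
* Correspondence gating and the inlier rule use strict `<`.
* solve_point_to_point requires ≥ 3 non-collinear pairs (rank check on the
  cross-covariance); solve_point_to_plane requires ≥ 6 pairs and returns
  the minimum-norm update when rank-deficient.
* Zero correspondences mid-ICP return the best-so-far transform with a
  failure flag; a search whose every threshold yields zero fitness raises
  a registration-failure error.
* Rendering ties (identical depth at a pixel) resolve to the lower point
  index; rasterization is deterministic and lazy, so providers that track
  geometry directly never pay for it.
* All generator and jitter randomness flows from explicit integer seeds.

## Problem sizes

Default test and reproduction sizes were chosen to keep a complete run in
minutes on one CPU: 100k-point heads for the ten-fixture reproduction
(≈15–25 s per fixture end-to-end), 20–30k for unit-level fixtures. Voxel
downsampling bounds the per-iteration ICP cost regardless of input size.

## Known limitations

* The method is strictly rigid; expression changes between CBCT and scan
  acquisition (the dominant real-world error source) are not modeled.
* The pose loop needs a successful landmark detection on the initial
  view; real deployments must frame the face for the detector.
* Fitness depends on scan composition (how much non-face content the
  sensor captured), so it is comparable across protocols only as a
  relative quantity.
* The fitness-versus-threshold collapse point tracks the residual
  initialization error and the sampling scale; with a very precise
  initialization the curve can stay flat across the whole search range,
  in which case the tie-breaking rules (lower RMSE, lower threshold)
  decide.
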