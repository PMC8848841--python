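# Methods

## Model and assumptions

The ulnohumeral joint is treated as a rigid articulation: at each pose of
a flexion sequence the ulna's motion relative to the (fixed) humerus is
summarized by an instantaneous rotation axis.  The estimator exploits the
articular geometry of the greater sigmoid notch, which wraps the humeral
trochlea as a near-cylindrical concave arc: cross-sections of the notch
perpendicular to the mediolateral direction are near-circular arcs whose
centers line up along the joint's rotation axis at that pose.  The method
therefore assumes

- rigid bones (no cartilage deformation),
- a notch that is locally cylindrical over the ±5 mm band sampled by the
  offset planes,
- three registered landmarks lying in one notch cross-section, so the
  landmark-plane normal is the mediolateral direction.

The axis of one pose is a property of that pose's articular surface; it is
*not* the finite helical axis between two poses.  On an ideal hinge the two
coincide, which is exactly what the oracle-equivalence test checks.

## Axis construction

1. **Landmark plane.** Plane through the three notch landmarks; rejected
   if the triangle area is below 1e-6 mm² (collinear registration).
2. **Offset planes.** 11 planes at 1 mm spacing, symmetric about the
   landmark plane (−5 … +5 mm) along its normal.  Sidedness of the offsets
   is not observable from the construction, so the symmetric choice is the
   default; spacing and count are configurable.
3. **Section curves.** `trimesh` computes the plane–mesh intersection
   segments; these are chained into polylines by endpoint matching
   (KD-tree, 1e-7 mm tolerance).  A plane through a closed bone surface
   yields closed loops containing both the articular arc and the far
   cortex, so each loop is resampled at uniform arc length (0.75 mm),
   split at sharp corners, and the smooth piece nearest the landmark
   centroid is kept.  Corners are detected as turning angles above 50°
   measured over a ±4 mm chord baseline — long enough that 0.2 mm vertex
   noise (≈4° of angular noise at this baseline) and the gentle curvature
   of a 12 mm arc (≈19°) stay well below threshold while genuine surface
   creases (≈90°) stand out; the baseline should stay below about a third
   of the notch radius.  A margin of one quarter baseline is discarded
   around each corner.
4. **Circle fits.** Points are projected into the section plane; the Kåsa
   algebraic fit seeds one Gauss–Newton refinement of the geometric
   (radial) residual.  A single refinement step keeps the estimator
   deterministic and free of iteration-count sensitivity; on exact data
   the result is exact, on partial arcs the refinement removes the
   algebraic fit's radius bias.  Arcs subtending < 60° as seen from the
   algebraic center are rejected as ill-conditioned.
5. **Axis.** Total-least-squares line (first principal axis of the
   centered covariance) through the 11 circle centers; the rms
   perpendicular distance of the centers is the axis residual, and a
   center spread below 1 mm along the principal direction is rejected as
   degenerate.  The direction sign is fixed toward the lateral (+X) side
   of the humeral frame so downstream signed angles are consistent.

### Independent oracle

`helical_axis_oracle` registers two vertex-corresponding poses with the
closed-form SVD solution of the orthogonal Procrustes problem and extracts
the finite helical (screw) axis from the resulting rigid transform.  It
shares no code path with the notch construction and serves as the
cross-check in tests; rotations below 1° are flagged unreliable because
the axis direction of a near-identity rotation is numerically meaningless.

## Humeral landmark frame

X̂ = unit(lateral center − medial center); Ẑ = unit(X̂ × shaft), which is
perpendicular to both the transcondylar axis and the humeral shaft and
points posteriorly for anatomically consistent right-side input;
Ŷ = Ẑ × X̂, the component of the shaft direction orthogonal to X̂.  This
triad is exactly orthonormal and right-handed by construction.  A
`side="left"` flag mirrors X̂ so it still points laterally.  The supplied
posterior hint is used only as a consistency check: if it disagrees with
Ẑ the input is almost certainly from the wrong side, and a warning is
issued rather than silently flipping the handedness.  The frame origin is
the medial aspect center projected onto the bone surface along −X̂
(Möller–Trumbore ray cast; the aspect center itself if the ray misses or
no mesh is supplied).

Flexion is the dihedral angle between a coronal plane of the proximal ulna
(the plane containing the rotation axis and the direction from the axis to
the bone centroid) and the humeral coronal plane.  A single pair of planes
only determines the angle up to the arccos fold at 90°; sequences are
unfolded by tracking the signed dihedral about X̂ with frame-to-frame
normal continuity, referenced to the first frame so 0° is the
maximum-extension pose.

## Intersection mapping

Pierce points are line–plane intersections with each aspect circle's plane
(the epicondylar faces are modeled as planar disks; intersecting the
triangulated surface instead is available as an option).  Normalized
coordinates divide the frame-axis components by the aspect radius; the
medial side is referenced to the frame origin and the lateral side to the
lateral aspect center expressed on the same axes (a config switch selects
the single-medial-origin reading instead).  Quadrants assign exact zeros
to the positive (posterior/superior) class with a recorded tie flag, for
determinism.  Axis angles are measured after projecting the direction into
the coronal (XY) and horizontal (XZ) planes; unsigned values in [0°, 90°]
are reported, signed values retained for trend direction.  The isometric
window keeps frames with |y%| ≤ 20 and |z%| ≤ 20 on both sides
simultaneously.

## Statistics

`linear_trend` is ordinary least squares from the normal equations with an
exact-t two-sided test on the slope (n−2 df) — the t distribution rather
than the normal approximation matters at ~30 frames per sequence.
`sample_size_two_means` implements the two-group normal-approximation
formula n = ⌈2 (z₁₋α/2 + z_power)² σ²/Δ²⌉ per group, the standard reading
of a "multi-sample mean comparison" sample-size computation; with
α = 0.05, power 0.8, means 2.6° and 5.7°, σ = 2.2° it gives n = 8.  The
formula is mildly optimistic relative to the exact noncentral-t power
(≈0.78 at the formula's n for a unit effect), which the test suite
documents by comparing simulation against the noncentral-t closed form.
Angle summaries are linear mean/SD/range; the angles summarized stay well
below 90°, so no circular statistics are needed.  Trend regressions pool
frames by default; per-sequence use is a flag away.

## Synthetic data: what it emulates and what it does not

The generator produces the study conditions the estimators are validated
under: a 30-frame sequence over a 106.5° range of motion (one pose per
second of a 30 s acquisition at the cohort's mean ROM), a notch of radius
12 mm and width 20 mm spanning a 170° arc, aspect radii 10 mm (medial) and
8 mm (lateral), a 50 mm transcondylar separation, and 1 mm mesh
resolution — anatomically plausible values, configurable, chosen once.
Three trajectory presets:

- **fixed_axis** — pure hinge about the transcondylar axis;
- **drifting_axis** — the signed horizontal tilt sweeps quadratically from
  0 to −47° (unsigned 0 → 47°, increasing with flexion) and the coronal
  tilt to 12.3°, while the axis point migrates on the medial aspect plane
  so the medial pierce point moves anterior-inferior → posterior-superior
  and the lateral pierce point posterior → anterior.  The quadratic shapes
  keep the lateral migration monotone and place the ±20 % window crossing
  at 31° flexion (medial z is the binding coordinate), so exactly the nine
  lowest-flexion frames are isometric-window members.  A 47° horizontal
  tilt over a 50 mm transcondylar span moves the lateral pierce point by
  ~54 mm (~670 % of the lateral radius) at full flexion — large axis
  obliquity and near-center pierce points are mutually exclusive at this
  geometry, so the window necessarily closes early;
- **noisy** — fixed axis plus 0.2 mm i.i.d. Gaussian vertex noise, seeded
  per frame.

The meshes are exact prisms and frustums: no trochlear ridge saddle, no
cortical thickness variation, no osteophytes, no segmentation artifacts,
and the vertex noise is white rather than spatially correlated like CT
partial-volume error.  Passing recovery tests therefore demonstrates the
estimator's correctness and its noise robustness at realistic amplitudes,
not its behavior on pathological anatomy; landmark jitter (seeded) covers
manual registration error separately.

## Segmentation

Single-threshold binarization (≥ threshold) followed by marching cubes at
iso 0.5 in world millimetres; the largest connected surface component is
kept so that several bones exceeding the threshold still yield per-bone
models.  No HU threshold default is provided — it is acquisition-specific
and must be supplied.  Marching cubes on a binary field overestimates
surface area by the staircase effect (~8 % on a sphere), so five
volume-preserving Taubin smoothing iterations are applied by default
(area error ~0.6 %, volume preserved to ~1 %); `smooth_iterations=0`
yields the raw isosurface.  A voxelize → segment → mesh round trip on the
synthetic ulna recovers the notch radius within one voxel.

## Numerical choices and degenerate inputs

Millimetres and degrees throughout.  Unit-vector normalization rejects
norms below 1e-12; collinear landmark triples, axis-parallel aspect
planes, constant regressors, equal-mean power specs, sub-60° arcs and
sub-1 mm center spreads all raise typed errors rather than returning
garbage.  Pipeline runs are pure functions of (files, config, seed):
per-frame failures are recorded and skipped, and the exit code is 1 when
more than 20 % of frames fail, 2 on fatal errors.

## Problem sizes

The default study uses 30 frames per sequence, ~2.3 k vertices per ulna
mesh, 11 sections per frame, 1000 null simulations for the type-I check
and 100 random rigid transforms for frame equivariance; the full test
suite runs in well under a minute and `scripts/acceptance.py` in a few
seconds on one CPU.

## Known limitations

- Ligament length change along the reconstructed graft is out of scope;
  the isometric window is a proxy based on axis-center proximity.
- The radiohumeral joint, non-rigid motion and automatic landmark
  detection are not modeled.
- Flexion-angle unfolding relies on frame-to-frame continuity and assumes
  pose increments well below 90° per frame.
- The per-frame axis of a drifting trajectory is a pose property; finite
  helical axes between widely spaced frames will differ by construction.
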