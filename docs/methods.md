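# Methods

`maskforge` turns a facial surface scan and nine anatomical landmarks into
a set of watertight, 3D-printable respirator-mask components. This note
documents the geometric procedure, the choices made where the design was
genuinely open, and what the synthetic test data does and does not show.

## Inputs and conventions

All geometry is in millimetres; no unit auto-detection is performed (a
scan in metres fails the landmark-proximity validation loudly). The face
scan is an open 2-manifold triangle shell in OBJ format, as produced by
stereophotogrammetry. The nine landmarks are the lateral and medial canthi
of both eyes (Ex(r), En(r), En(l), Ex(l)), the radix Ra, nasal tip Ntp,
philtral crest Pc, pogonion Pg and menton M, supplied as JSON or CSV with
either the clinical names ("Ex(r)") or identifier-safe aliases (`Ex_r`).

## Reference planes and control points

Nine planes are derived from the landmarks:

* **MF** (midface / midsagittal): through Ra, Ntp, Pg.
* **VP** (vertical): through the lateral canthi, perpendicular to MF.
* **HP** (horizontal): through Ra, perpendicular to MF and VP.
* **LHP**, **CHP**: parallels of HP through Pc and Pg.
* **HLCP**, **HRCP**: parallels of MF through Ex(l), Ex(r).
* **CLP**, **CRP**: parallels of MF through the canthus midpoints
  (Ex+En)/2 of each eye.

The textbook construction of VP — the unique plane through two points
perpendicular to another plane — degenerates exactly when the two canthi
are mirror images across MF: the canthus segment is then parallel to the
MF normal, every plane through it is perpendicular to MF, and for
*near*-symmetric faces the construction is numerically dominated by the
millimetre-scale asymmetry of the canthi (it can even return a horizontal
plane if the canthi differ mainly in depth). Because every plausible face
is close to this degenerate configuration, VP is built in a regularized
form: it passes through the canthus midpoint with normal `n_MF × v`,
where `v` is the unit vector from the menton to the radix projected into
MF (the facial "up"). This plane is always perpendicular to MF, contains
a mirror-symmetric canthus pair exactly, and otherwise misses each
canthus by at most half their asymmetry about MF — a quantity on the
scale of landmark placement error. Canthi further than 10 mm from the
plane are rejected as anatomically implausible input.

Plane normals carry fixed anatomical signs (MF family toward the
anatomical left, i.e. the Ex(l) side; HP family toward superior; VP
toward anterior), and an orthonormal **anatomical frame**
(lateral-left, superior, anterior) is assembled from them, with the
anterior sign fixed by requiring the nasal tip to lie anterior of the
mesh centroid. The frame gives "translated anteriorly" an unambiguous
meaning.

The six seal-line control points are C1 = Ra, C4 = M, and four
plane-pair/surface intersections: C2 (HRCP∧LHP), C3 (CRP∧CHP),
C5 (CLP∧CHP), C6 (HLCP∧LHP). A plane-pair line can cross a curved face
shell more than once (or graze scan edges); among all crossings the
**anterior-most** one is taken, since the seal runs on the facial front
and posterior crossings are scan-edge artifacts.

## Seal curve

A periodic cubic spline (chord-length parameterization) interpolates
C1…C6 in cyclic order — the seal loop closes over the radix — and is
sampled into a dense polyline (default n = 200, with every control point
kept as an exact sample). The polyline is attached to the face by
iterated closest-point projection with one Laplacian smoothing pass per
iteration (projection tolerance 0.05 mm, at most 10 iterations); the six
control-point samples are pinned so the Table-derived geometry is honored
exactly. Closest-point projection (rather than normal-ray casting) is
robust on open shells with holes. The attached curve must sit within
0.1 mm of the surface, keep consecutive samples under 5 mm apart, and be
simple in the anterior view.

## Mask body

* The **translated curve** is a rigid copy of the base curve moved
  anteriorly by `ratio · |Ra − Ntp|` (default ratio 0.5), creating the
  clearance over the nasal dorsum.
* The **filter base** is a circle (default radius 30 mm, configurable or
  replaceable by a user outline) on the plane parallel to VP through the
  point 20 mm anterior of the nasal tip.
* **Lofts** join base → translated curve → filter circle as ruled
  surfaces. Profile correspondence is chosen by winding alignment and the
  circular shift minimizing total rail length; the stitched surface keeps
  interior rings at ≈3 mm spacing so its triangulation is near-isotropic,
  which the later normal offset needs. The result is an annulus-like open
  tube (Euler characteristic 0) with exactly two boundary loops: the
  seal line and the filter opening.
* **Shelling** offsets the surface 2 mm outward along averaged vertex
  normals (two one-ring smoothing passes regularize the normal field) and
  closes both boundary loops with side walls. Offsetting outward leaves
  the skin-side seal geometry untouched. An offset that folds the surface
  over itself (concave radius smaller than the thickness) is rejected
  with an error rather than silently self-intersecting.

## Soft rim and connection parts

The seal rim is a tube of circular cross-section (default radius 3 mm,
32 sections) swept along the base curve with parallel-transported frames
(holonomy twist distributed uniformly so the loop closes), minus the mask
body. No robust exact mesh-boolean backend is available in this
environment, so the subtraction is voxel-based: both solids are
rasterized onto a 0.5 mm grid (surface sampling at half-pitch density,
one-voxel closing, cavity fill), combined as boolean arrays with the body
dilated one voxel (biasing toward a strict difference), and re-meshed
with marching cubes. The rim is therefore accurate to voxel scale —
well below print tolerance — and guaranteed watertight.

Four slotted strap-anchor tabs (16×12×3 mm frames with a 9×5 mm slot)
are placed at configurable arc-length fractions of the base curve —
defaults sit pairwise near the cheek (C2/C6) and chin (C3/C5) regions —
oriented along the outward radial direction. The union with the body is a
multi-solid concatenation of closed meshes: zero boundary edges, exact
volume bookkeeping, and a placement that keeps each tab tangent to the
outer shell. A tab whose position would reach the filter port is an
error.

## Filter housing and assembly

Seven parts are exported per build: washer, soft rim, mask body, grating,
inner filter cover, outer filter cover, and female locking ring — listed
in the manifest in assembly order. The five housing parts are simplified
parametric solids (annuli, capped discs, a spoked grating) dimensioned to
nest concentrically with a configurable radial clearance (default
0.3 mm); screw threads are approximated by smooth press-fit cylinders,
since thread mechanics are outside the design algorithm. The grating's
open-area fraction is reported and kept within [0.3, 0.7]. Any generated
part may be replaced by a user-supplied STL (validated for
watertightness).

## Synthetic faces

The test bed is a parametric face: an anterior half-ellipsoid height
field (half-axes 70×90×80 mm) with a Gaussian nose ridge (height 25 mm)
peaking at the nasal tip, a chin bulge (10 mm) peaking at the pogonion,
and a vertical shear that levels the radix and menton depths the way an
upright scan subject presents. All nine landmarks are snapped to exact
mesh vertices (Ntp to the globally most anterior vertex), so on-surface
invariants are exact rather than tolerance-based. With asymmetry 0 the
vertex set is bitwise mirror-symmetric, which drives the whole pipeline
to mirror-symmetric control points and mask bodies — the main symmetry
check of the test suite.

Two perturbation models exercise robustness:

* `jitter_landmarks` re-places each landmark at a mesh vertex within
  2 mm — the reported accuracy of manual cephalometric annotation. Over
  20 seeds the control points move less than 5 mm and every pipeline run
  completes; this is the robustness the design procedure claims.
* `perturb_face` displaces the whole shell along vertex normals by a
  spatially smoothed random field (≈1 cm correlation length, matching
  scan-reconstruction error). Note that surface noise of σ = 2 mm also
  carries the landmarks with it (up to ≈2σ), so downstream control-point
  shifts reach ≈6 mm — larger than the landmark-only case, and the test
  suite asserts the honestly measured bound. With shorter correlation
  lengths a 2 mm outward offset becomes geometrically impossible
  (concave radii below the shell thickness), which real Vectra-class
  scans do not exhibit.

What the synthetic face does **not** emulate: eye/mouth holes and ragged
scan borders, skin texture, population shape variation, and genuinely
asymmetric anatomy beyond the smooth `asymmetry` parameter. Passing
tests therefore demonstrate correctness of the geometric constructions,
not fit quality on real faces.

## Numerical choices

* On-surface tolerance 0.1 mm; plane residuals 1e-6 mm; unit normals to
  1e-9 — far below scan noise, far above double-precision error.
* Binary STL is float32: coordinates at ~100 mm survive a round trip to
  ~1e-5 mm. OBJ is written at full precision (1e-6 round trip).
* Spatial queries (closest point, ray casting, containment) are
  k-d-tree-accelerated pure numpy; booleans are voxel-based as described.
  Both are deterministic, and the whole pipeline is byte-deterministic
  for fixed inputs and configuration (the report timestamp aside).
* Shell thickness is verified by inward ray casting at 500 area-weighted
  random surface points (fixed seed); the median must lie in 2 ± 0.2 mm.
* Default problem sizes — 101×101 face grid (~15k triangles), 200 curve
  samples, 0.5 mm voxel pitch — were chosen so a full build completes in
  well under a minute; robustness sweeps use a 1 mm pitch for the rim.

## Known limitations

* The voxel boolean rounds the rim's sharp subtraction edges to voxel
  scale and slightly under-fills it (the one-voxel dilation bias).
* Shelling fails deliberately rather than degrading when the requested
  thickness exceeds the local concave curvature radius.
* Housing dimensions are engineering defaults, not reproductions of the
  original online STL (which has no published dimensions).
* The click-lock cover variant is deliberately not implemented; the
  screw-drive design is the one that survived physical testing.
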