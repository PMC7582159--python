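# Methods

This note documents the models, parameters, and numerical choices behind
`bifurcate3d`, and what the synthetic phantoms do and do not establish about
real data.

## Geometry model and assumptions

The reconstruction assumes: (i) the angiographic centerlines are metrically
accurate in 3D (they are consumed, not estimated); (ii) OCT frames are rigid
planar sections that may only rotate about the catheter axis — no in-plane
deformation and no pullback-speed jitter; (iii) pullback spacing is uniform
(default 0.2 mm/frame, i.e. 5 frames/mm); (iv) each pullback covers its
branch so that the carina frame exists and is annotated; (v) the lumen
contour in each frame is a simple closed polygon, counter-clockwise after
loading, star-shaped about its centroid to good approximation (true for
coronary lumens, required only by the implicit merge).

Frames are embedded so the branch centerline passes through the **lumen
centroid** of each contour, not the catheter center: OCT catheters sit
eccentrically, and anchoring the centroid is what makes the zero-noise
phantom reconstruction exact.  The catheter-center offset is retained per
frame because the carina direction reference emanates from it.

## Twist handling

The catheter encodes no absolute roll, so in-plane orientation is split into
three rigidly composed parts:

1. relative frame-to-frame roll, restored by the overlap corrector;
2. zero transport twist, guaranteed by double-reflection rotation-minimizing
   frames along each branch (tangents from a not-a-knot cubic-spline
   derivative of the resampled polyline — central differences carry a
   systematic bias on helical curves that accumulates as spurious twist;
   with spline tangents the frames track a dense parallel-transport
   reference to well under 0.5° over tens of mm);
3. one global roll per branch, fixed at the carina by rotating all frames
   until the carina direction reference is parallel to the in-plane
   projection of the carina reference point.

The alignment condition is *direction parallelism measured from the frame
origin*.  With an eccentric catheter this leaves a small parallax roll bias
(the reference direction actually emanates from the catheter center, not the
origin); serial areas and shape ratios are insensitive to roll, so the
validation metrics are unaffected, but per-point surface error under heavy
jitter includes this term.  A ray-through-point alignment would remove it at
the cost of a more brittle contract.

## Orientation corrector

Parameters: `threshold_fraction` (default 0.10) — the mismatch gate as a
fraction of the mean frame area; `max_range_deg` (default 180) and the fixed
0.5° search increment.  The search is exhaustive over the ±range grid and
deterministic; near-ties (within 1e-9 relative) resolve to the smallest
|rotation|, which makes the corrector an exact no-op on rotationally
symmetric (circular) lumens and on nested consecutive contours.  Corrections
are applied cumulatively to all downstream frames: pairwise mismatch is
always evaluated against the already-corrected predecessor, so a single pass
removes a persistent jump without re-introducing it at the next pair.
Frame 0 (most distal) anchors the chain.

Two identifiability limits are worth knowing.  First, rotation is
unobservable on circular contours; phantoms default to ellipticity 0.7 so
correction is testable.  Second, where the lumen tapers quickly the smaller
contour nests inside its neighbour and the overlap objective has a plateau —
rotation is locally unidentifiable there, which is why the rotation-recovery
benchmark uses a constant-radius elliptical pullback.  Recovery accuracy is
quoted in the gauge the pipeline actually fixes (roll relative to the carina
frame); with the gate disabled it is bounded by the 0.5° grid quantization
plus the unresolvable sub-grid component of the artifact walk, measured at
RMS 0.5–0.95° over 200 frames across seeds.  With the default 10% gate, a
10° jump on a 0.7-ellipticity lumen produces only ~8% mismatch and does not
trigger; the default is deliberately conservative (small physiologic
frame-to-frame change should not cause rotation), and the threshold is a
first-class parameter.

## Surface merge

Smooth branch merging is implemented as: per-branch loft (rings
resampled to `samples_per_ring` = 128 points, start indices chosen to
minimize summed point-to-point distance — prevents loft twist), then an
implicit union.  Each tube becomes a radial field r(point) − r_ring(s, θ)
(per-ring polar profiles about the centerline, bilinear in station and
angle, intersected with the axial slab of its rings), the union is the
pointwise minimum of the two fields, and the zero level set is extracted by
marching cubes at `pitch_mm` (default 0.1 mm) and relaxed with
`smooth_iters` = 10 Taubin passes (λ = 0.5, ν = 0.53; volume drift is
checked to stay under 1%).  The marching-cubes grid origin is offset by an
irrational fraction of the pitch so no lattice plane coincides with a flat
end cap (exact node zeros produce degenerate non-manifold output).  The
result is watertight and 2-manifold by construction and symmetric in the two
branches.  Faces within 2 mm of the carina reference are labelled
`carina-blend`; cross-section fidelity is not asserted there, because the
union necessarily departs from single-branch rings near the ostium.

The proximal-MV overlap rule drops SB rings proximal of the SB carina point
before the union, so the shared proximal segment derives only from the
straighter MV pullback.

Accuracy at the defaults, measured on noise-free phantoms: Hausdorff
distance ≤ 0.05 mm against the analytic truth restricted to the imaged
segment, cross-section areas within 0.5% outside the blend zone.

## Metrics

* **Serial areas**: plane sections every `section_step_mm` (default 2 mm)
  through the centerline point with the local tangent as normal, keeping the
  loop containing the centerline point.  For method comparison both meshes
  are sectioned along the same (reference) centerlines; SB sections start
  2 mm distal of the carina because proximal SB stations either cut the
  shared trunk or miss the lumen in the carina wedge.
* **z-score**: sample SD (n−1).  SD-of-the-mean (SEM) would not standardize
  the series to unit spread, which is the point of the normalization.
* **Lumen shape**: boundary resampled to ≥ 512 points; X is the longest
  boundary chord, Y the extent of boundary projections perpendicular to X
  (`--y-mode chord` offers the maximal perpendicular chord instead; the two
  agree on convex sections).
* **Bifurcation angles**: limb directions are tangent means over
  `angle_window_mm` (default 5 mm), each window starting after a carina
  clearance (default twice the carina-reference-to-centerline distance,
  roughly one lumen diameter).  The clearance exists because the carina
  point sits about one lumen radius distal of where the two branch
  centerlines converge; a window starting exactly there mixes the junction
  bend into the proximal-MV direction (~8° bias on a 154° phantom).  The
  exact windowed construction is this package's own stand-in for an
  otherwise unspecified angle definition; both parameters are exposed.
* **Agreement**: OLS with the reference method as response; Bland–Altman
  with mean ± 1.96 sample SD.  On the bundled bench angle table (15 pairs)
  these reproduce mean difference 0.004°, r² = 0.994, y = 1.04x − 4.64.

## Phantom generator

The generator emulates the bench validation conditions: 40 mm MV coverage at
0.2 mm/frame (200 frames), MV radius 1.5 mm, SB radius 1.0 mm, ellipticity
0.7, bifurcation angles defaulting to (A, B, C) = (151°, 55°, 154°)
(realizable coplanar triples satisfy A + B + C = 360° or one angle equal to
the sum/difference of the others).  Branch centerlines are straight limbs
joined by a short tangent-continuous fillet (1 mm); the SB centerline shares
the MV trunk proximal of the junction, as a real SB pullback does.  The
carina reference is solved exactly on the ridge where the two tube surfaces
intersect.  The SB radius hands off from trunk to branch over a 2 mm
smoothstep (no real pullback shows a radius step between consecutive
frames).

Noise model (all driven by one seed): frame roll is a Gaussian random walk
(`walk_sd_deg` per frame) plus sparse persistent jumps (`jump_prob`,
`jump_sd_deg`), the catheter center is the centroid plus a slowly drifting
offset (i.i.d. noise smoothed with a σ = 10-frame Gaussian kernel, rescaled
to RMS `centroid_jitter_mm` = 0.3) — an i.i.d. offset would make successive
frames differ by a pure translation that a rotation-only corrector cannot
and should not chase.

What passing phantom tests do **not** show about real data: segmentation
error and drop-out, non-rigid cardiac deformation between frames,
pullback-speed variation, angiographic centerline error, foreshortening at
sharp bends, and real ostium geometry (the phantom uses its per-branch
ellipse through the junction zone rather than the true merged section, which
is one reason the 2 mm carina blend zone is excluded from area checks).

## Problem sizes and tolerances

Tests and the acceptance script run phantoms at 24–40 mm MV length, merge
pitch 0.1–0.15 mm, and 15 k surface samples for Hausdorff estimates — sizes
chosen so the full suite completes in a few minutes while every bound
(Hausdorff 0.2 mm, 3% area, 0.5° angles, 1.0° RMS recovery) is met with a
factor-2+ margin.  Degenerate inputs rejected with diagnostics include:
duplicate centerline points, self-intersecting or sub-3-point contours,
carina annotations off the carina frame, disjoint or fully nested branch
tubes, wall contours crossing their lumen, and constant series passed to the
z-score.
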