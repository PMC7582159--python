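# bifurcate3d

3D reconstruction of coronary artery bifurcations by fusing invasive
angiography with optical coherence tomography (OCT) of both the main vessel
(MV) and the side branch (SB).

Neither modality alone captures a bifurcation: 3D quantitative coronary
angiography (3D QCA) recovers the 3D course of the vessel centerlines but
not the true lumen shape, while OCT images the lumen cross-section at
5 frames/mm but has no 3D positional reference and suffers rotational frame
artifacts from cardiac motion (acquisition is not ECG gated).  `bifurcate3d`
combines them: the angiographic centerlines form the *backbone* of the
reconstruction, the OCT contours supply the vessel shape, and the carina —
the ridge where the two daughter lumens split — anchors the registration.
The intended users are researchers in intravascular imaging and coronary
biomechanics who need watertight, patient-specific bifurcation lumen (and
wall) surfaces for morphometric analysis, CFD, or stenting simulation.

## Method

Inputs: MV and SB centerlines (ordered 3D polylines, mm) plus one carina
reference point **C** from 3D QCA; one segmented OCT pullback per branch
(closed lumen polygons in catheter-frame coordinates, 0.2 mm/frame) with the
carina frame and its in-frame carina location annotated.

1. **Backbone** — centerlines are arc-length parameterized; **C** is
   projected onto each branch giving carina points **A** (MV) and **B**
   (SB); twist-minimizing frames (double-reflection rotation-minimizing
   frames) are transported along each branch.
2. **Frame orientation correction** — successive OCT frames image nearly the
   same lumen and can only rotate about the catheter center.  Whenever the
   symmetric-difference area between a frame and its corrected predecessor
   exceeds a threshold fraction of the mean frame area, the frame is rotated
   on a 0.5° grid (±180°) to minimize that area, and the correction is
   propagated cumulatively downstream.
3. **Fusion** — the carina frame is placed at **A**/**B**, the remaining
   frames at their known pullback distances along arc length, each
   perpendicular to the centerline with the lumen centroid on it.  A single
   rigid rotation φ about the frame normals then aligns the carina direction
   reference (catheter center → in-frame carina point) with **C**; all
   frames rotate together, preserving relative orientation.
4. **Surface** — each branch's rings are lofted into a tube with
   minimal-twist ring correspondence; the MV and SB tubes are merged into a
   single watertight, 2-manifold surface (implicit tube fields, boolean
   union as a pointwise minimum, marching-cubes extraction,
   volume-preserving Taubin smoothing).  Proximal to the carina both
   pullbacks imaged the same lumen; since the MV pullback is straighter, the
   proximal segment is reconstructed from MV frames only.  An optional wall
   channel replays the identical corrections to give nested lumen/wall
   surfaces.
5. **Metrics** — serial cross-section areas every 2 mm (z-score normalized,
   (a − μ)/σ, to remove between-modality scale offsets), the lumen-shape
   ratio Y/X (longest chord X, perpendicular extent Y), and bifurcation
   angles A (proximal MV–SB), B (distal MV–SB), C (proximal–distal MV) from
   tangent-averaged limb directions.  Method comparison uses ordinary least
   squares (r² = squared Pearson correlation) and Bland–Altman limits of
   agreement (mean difference ± 1.96 SD).

Because no paired angiography + segmented-OCT bifurcation dataset is
publicly deposited, the package ships a first-class phantom generator:
analytic Y-shaped lumens with prescribed angles, radius profiles (constant,
tapered, cosine stenosis) and ellipticity, plus simulated pullbacks with
ground-truth rotation artifacts, so every pipeline stage is testable.

## Worked example

Generate a noisy synthetic bifurcation (40 mm MV pullback with a proximal
stenosis, tapering SB, rotation-artifact walk 0.3°/frame with sparse 8°
jumps), reconstruct it, and compare against the bundled ground truth.
First the phantom spec, `demo_spec.json`:

```json
{
  "mv_radius_profile": {"kind": "stenosis", "radius": 1.5, "depth": 0.4,
                        "extent": 12.0, "center": 12.0},
  "sb_radius_profile": {"kind": "tapered", "r_start": 1.1, "r_end": 0.8,
                        "length": 20.0}
}
```

```bash
bifurcate3d phantom --out demo/bundle --spec-json demo_spec.json --seed 3 \
    --walk-sd-deg 0.3 --jump-prob 0.02 --jump-sd-deg 8
bifurcate3d reconstruct demo/bundle --out demo/recon
bifurcate3d compare demo/recon/lumen.stl demo/bundle/ground_truth_lumen.stl \
    --bundle demo/bundle --out demo/cmp
```

The reconstruct step logs its per-branch summary:

```
INFO bifurcate3d: MV: 200 frames, 7 pairwise corrections, phi=3.36 deg
INFO bifurcate3d: SB: 200 frames, 11 pairwise corrections, phi=35.16 deg
```

meaning 7 (MV) and 11 (SB) frame pairs tripped the mismatch gate and were
re-aligned, and the whole SB frame set was rotated by φ = 35.2° to bring its
carina annotation onto the carina reference.  `demo/cmp/comparison.json`
then contains, per branch, the z-scored serial-area regression and the
lumen-shape Bland–Altman against the ground-truth surface:

```
MV r2=1.000 slope=1.000 intercept=0.000 shape_mean_diff=-0.0005
SB r2=1.000 slope=1.000 intercept=-0.000 shape_mean_diff=0.0014
angles [150.97, 55.0, 154.03]
```

i.e. the noisy reconstruction reproduces the ground-truth area profile
essentially exactly (serial areas are insensitive to residual roll), the
cross-section shape ratio agrees to ~0.001, and the recovered bifurcation
angles match the phantom's prescribed (151°, 55°, 154°) within 0.03°.

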