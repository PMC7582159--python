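"""Lofting, implicit-union merging, wall reconstruction."""

import numpy as np
import pytest
import trimesh

from bifurcate3d.backbone import (
    BifurcationBackbone, Centerline, arc_length_parameterize, project_carina,
)
from bifurcate3d.fusion import place_frames
from bifurcate3d.oct_frames import Contour, FrameStack
from bifurcate3d.phantom import simulate_pullback
from bifurcate3d.surface import (
    hausdorff_distance, loft_branch, merge_bifurcation, reconstruct_wall,
)
import bifurcate3d.metrics as metrics

from conftest import ellipse_contour


def tube_frameset(centerline_pts, radius=1.5, spacing=0.2, label="MV", n_pts=64):
    cl = arc_length_parameterize(Centerline(centerline_pts, branch_label=label))
    n = int(np.floor(cl.total_length / spacing)) + 1
    contours = [Contour(points=ellipse_contour(a=radius, ratio=1.0, n=n_pts))
                for _ in range(n)]
    stack = FrameStack(contours=contours, spacing=spacing, branch_label=label,
                       carina_frame_index=n // 2,
                       carina_point_2d=[radius, 0.0])
    return place_frames(stack, cl, carina_param=(n // 2) * spacing * 0 +
                        cl.total_length - (n // 2) * spacing), cl


def straight_pts(length, direction=(0, 0, 1.0), origin=(0, 0, 0), n=None):
    direction = np.asarray(direction, float)
    direction /= np.linalg.norm(direction)
    n = n or int(length * 10) + 1
    t = np.linspace(0, length, n)
    return np.asarray(origin) + t[:, None] * direction


class TestLoftBranch:
    def test_cylinder_lateral_area(self):
        fs, _ = tube_frameset(straight_pts(10.0), radius=1.5)
        tube = loft_branch(fs, samples_per_ring=128)
        span = fs.stations[-1] - fs.stations[0]
        assert tube.area == pytest.approx(2 * np.pi * 1.5 * span, rel=0.01)

    def test_ring_cross_section_area_preserved(self):
        fs, _ = tube_frameset(straight_pts(5.0), radius=1.2)
        tube = loft_branch(fs, samples_per_ring=128)
        assert tube.rings is not None
        for r, frame in zip(tube.rings.input_areas, fs.frames):
            assert r == pytest.approx(Contour(points=frame.contour2d).area,
                                      rel=0.01)

    def test_two_ring_prism_volume(self):
        fs, _ = tube_frameset(straight_pts(0.2, n=2), radius=1.0, spacing=0.2)
        assert len(fs.frames) == 2
        tube = loft_branch(fs, samples_per_ring=128)
        ring_area = tube.rings.input_areas[0]
        # convex hull closes the two open ends of the circular prism
        filled = tube.to_trimesh().convex_hull
        assert filled.volume == pytest.approx(ring_area * 0.2, rel=0.005)

    def test_single_frame_rejected(self):
        fs, _ = tube_frameset(straight_pts(10.0))
        fs.frames = fs.frames[:1]
        with pytest.raises(ValueError, match="at least 2"):
            loft_branch(fs)


def crossing_tubes(angle_deg=60.0, r_mv=1.5, r_sb=1.0, length=12.0):
    """Two straight tubes crossing at the MV midpoint."""
    mv_pts = straight_pts(length)
    th = np.deg2rad(angle_deg)
    sb_dir = np.array([np.sin(th), 0, np.cos(th)])
    cross = np.array([0, 0, length / 2])
    sb_pts = cross - sb_dir * 2.0 + np.linspace(0, length / 2 + 2.0, 80)[:, None] * sb_dir
    fs_mv, cl_mv = tube_frameset(mv_pts, radius=r_mv)
    fs_sb, cl_sb = tube_frameset(sb_pts, radius=r_sb, label="SB")
    carina = cross + np.array([r_mv * 0.9, 0, 0.4])
    s_mv, _ = project_carina(carina, cl_mv)
    s_sb, _ = project_carina(carina, cl_sb)
    backbone = BifurcationBackbone(mv=cl_mv, sb=cl_sb, carina_ref=carina,
                                   carina_mv=s_mv, carina_sb=s_sb)
    return fs_mv, fs_sb, backbone, cl_mv, cl_sb, sb_dir, cross


class TestMergeBifurcation:
    @pytest.fixture(scope="class")
    def merged_cylinders(self):
        fs_mv, fs_sb, backbone, cl_mv, cl_sb, sb_dir, cross = crossing_tubes()
        mv_tube = loft_branch(fs_mv)
        sb_tube = loft_branch(fs_sb)
        mesh = merge_bifurcation(mv_tube, sb_tube, backbone, smooth_iters=5,
                                 pitch=0.08)
        return {"mesh": mesh, "backbone": backbone, "mv_tube": mv_tube,
                "sb_tube": sb_tube, "fs_mv": fs_mv, "fs_sb": fs_sb,
                "sb_dir": sb_dir, "cross": cross, "cl_mv": cl_mv}

    def test_watertight_and_manifold(self, merged_cylinders):
        tm = merged_cylinders["mesh"].to_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert tm.euler_number == 2  # sphere topology
        assert np.all(tm.area_faces > 1e-12)

    def test_volume_matches_voxel_oracle(self, merged_cylinders):
        mesh = merged_cylinders["mesh"]
        backbone = merged_cylinders["backbone"]
        sb_dir = merged_cylinders["sb_dir"]
        fs_mv = merged_cylinders["fs_mv"]
        fs_sb = merged_cylinders["fs_sb"]
        # analytic voxel oracle of the union actually merged: full MV tube +
        # SB tube restricted to stations >= the SB carina parameter
        sb_keep = merged_cylinders["fs_sb"].stations >= backbone.carina_sb
        sb_origins = np.array([f.origin for f in fs_sb.frames])[sb_keep]
        sb_lo = sb_origins[0]
        sb_hi = sb_origins[-1]
        mv_lo = fs_mv.frames[0].origin
        mv_hi = fs_mv.frames[-1].origin
        h = 0.05
        pad = 1.6
        lo = np.minimum(mv_lo, sb_lo) - pad
        hi = np.maximum(mv_hi, sb_hi) + pad
        xs = [np.arange(lo[k], hi[k], h) for k in range(3)]
        gx, gy, gz = np.meshgrid(*xs, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

        def in_tube(p, a, b, r):
            axis = b - a
            L = np.linalg.norm(axis)
            axis = axis / L
            rel = p - a
            t = rel @ axis
            radial = np.linalg.norm(rel - t[:, None] * axis[None, :], axis=1)
            return (t >= 0) & (t <= L) & (radial <= r)

        inside = in_tube(pts, mv_lo, mv_hi, 1.5) | in_tube(pts, sb_lo, sb_hi, 1.0)
        vol_oracle = inside.sum() * h ** 3
        assert mesh.volume == pytest.approx(vol_oracle, rel=0.02)

    def test_union_commutes(self, merged_cylinders):
        flipped = merge_bifurcation(merged_cylinders["mv_tube"],
                                    merged_cylinders["sb_tube"],
                                    merged_cylinders["backbone"],
                                    smooth_iters=5, pitch=0.08)
        # implicit union is symmetric in the two fields by construction
        assert flipped.volume == pytest.approx(merged_cylinders["mesh"].volume,
                                               rel=0.001)

    def test_face_labels_cover_both_branches(self, merged_cylinders):
        labels = set(merged_cylinders["mesh"].labels)
        assert {"MV", "SB"} <= labels

    def test_disjoint_tubes_rejected(self):
        fs_a, _ = tube_frameset(straight_pts(6.0), radius=1.0)
        fs_b, cl_b = tube_frameset(
            straight_pts(6.0, origin=(10.0, 0, 0)), radius=1.0, label="SB")
        cl_a = arc_length_parameterize(Centerline(straight_pts(6.0)))
        backbone = BifurcationBackbone(mv=cl_a, sb=cl_b,
                                       carina_ref=[5, 0, 3], carina_mv=3.0,
                                       carina_sb=0.0)
        with pytest.raises(ValueError, match="do not meet|disconnected"):
            merge_bifurcation(loft_branch(fs_a), loft_branch(fs_b), backbone,
                              smooth_iters=0, pitch=0.1)

    def test_sb_inside_mv_rejected(self):
        fs_a, cl_a = tube_frameset(straight_pts(6.0), radius=2.0)
        fs_b, cl_b = tube_frameset(straight_pts(5.0, origin=(0, 0, 0.5)),
                                   radius=0.8, label="SB")
        backbone = BifurcationBackbone(mv=cl_a, sb=cl_b,
                                       carina_ref=[1.9, 0, 3], carina_mv=3.0,
                                       carina_sb=0.0)
        with pytest.raises(ValueError, match="degenerate overlap"):
            merge_bifurcation(loft_branch(fs_a), loft_branch(fs_b), backbone,
                              smooth_iters=0, pitch=0.1)

    def test_smoothing_volume_drift_below_1pct(self, merged_cylinders):
        raw = merge_bifurcation(merged_cylinders["mv_tube"],
                                merged_cylinders["sb_tube"],
                                merged_cylinders["backbone"],
                                smooth_iters=0, pitch=0.08)
        sm = merged_cylinders["mesh"]  # smooth_iters=5
        assert abs(sm.volume - raw.volume) / raw.volume < 0.01


class TestPhantomGeometryFidelity:
    def test_hausdorff_against_ground_truth(self, zero_noise_recon):
        hd = hausdorff_distance(zero_noise_recon["lumen"],
                                zero_noise_recon["gt_restricted"],
                                samples=15000)
        assert hd <= 0.2

    def test_carina_ridge_position(self, zero_noise_recon):
        gt = zero_noise_recon["gt"]
        mesh = zero_noise_recon["lumen"].to_trimesh()
        d = np.linalg.norm(mesh.vertices - gt.backbone.carina_ref, axis=1)
        assert d.min() <= 0.3

    def test_cross_section_area_fidelity(self, zero_noise_recon):
        gt = zero_noise_recon["gt"]
        lumen = zero_noise_recon["lumen"]
        worst = 0.0
        for branch, cl in (("MV", gt.backbone.mv), ("SB", gt.backbone.sb)):
            lo = 0.5 if branch == "MV" else gt.backbone.carina_sb + 2.0
            for s in np.arange(lo, cl.total_length - 0.45, 1.0):
                p = cl.point_at(s)
                if np.linalg.norm(p - gt.backbone.carina_ref) <= 2.0:
                    continue  # blend zone is waived
                poly = metrics.cross_section_polygon(lumen, p, cl.tangent_at(s),
                                                     keep_point=p)
                assert poly is not None, f"empty section {branch} {s}"
                truth = float(gt.analytic_area(branch, s))
                worst = max(worst, abs(poly.area - truth) / truth)
        assert worst <= 0.03


class TestReconstructWall:
    @pytest.fixture(scope="class")
    def dual_channel(self, gt_y):
        gt = gt_y
        mv = simulate_pullback(gt, "MV", centroid_jitter_mm=0.0, seed=21,
                               wall_scale=1.3)
        sb = simulate_pullback(gt, "SB", centroid_jitter_mm=0.0, seed=22,
                               wall_scale=1.3)
        from bifurcate3d.fusion import fuse_branch
        fmv = fuse_branch(mv, gt.backbone.mv, gt.backbone.carina_mv,
                          gt.backbone.carina_ref)
        fsb = fuse_branch(sb, gt.backbone.sb, gt.backbone.carina_sb,
                          gt.backbone.carina_ref)
        return gt, fmv, fsb

    def test_scaled_wall_volume_ratio(self, dual_channel):
        gt, fmv, fsb = dual_channel
        lumen, wall = reconstruct_wall(fmv, fsb, gt.backbone, pitch=0.12,
                                       smooth_iters=5)
        assert lumen.to_trimesh().is_watertight
        assert wall.to_trimesh().is_watertight
        assert wall.volume / lumen.volume == pytest.approx(1.3 ** 2, rel=0.05)

    def test_missing_wall_channel_rejected(self, dual_channel):
        gt, fmv, fsb = dual_channel
        import dataclasses
        no_wall = dataclasses.replace(fmv, wall2d=None)
        with pytest.raises(ValueError, match="wall"):
            reconstruct_wall(no_wall, fsb, gt.backbone)

    def test_zero_thickness_wall_rejected(self, dual_channel):
        gt, fmv, fsb = dual_channel
        import dataclasses
        same = dataclasses.replace(fmv, wall2d=[f.contour2d.copy()
                                                for f in fmv.frames])
        with pytest.raises(ValueError, match="zero-thickness"):
            reconstruct_wall(same, fsb, gt.backbone)

    def test_crossing_wall_rejected_with_frame_index(self, dual_channel):
        gt, fmv, fsb = dual_channel
        import dataclasses
        bad_wall = [w.copy() for w in fmv.wall2d]
        bad_wall[3] = bad_wall[3] * 0.5  # wall inside lumen at frame 3
        bad = dataclasses.replace(fmv, wall2d=bad_wall)
        with pytest.raises(ValueError, match="frame"):
            reconstruct_wall(bad, fsb, gt.backbone)
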