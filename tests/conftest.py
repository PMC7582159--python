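"""Shared phantom fixtures.

The expensive reconstructions are session-scoped and reused across unit and
acceptance tests; every random quantity is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from bifurcate3d.cli import RunConfig, reconstruct_bifurcation
from bifurcate3d.phantom import PhantomSpec, make_phantom, simulate_pullback


@pytest.fixture(scope="session")
def gt_small():
    """Compact bent bifurcation phantom (24 mm MV, 12 mm SB limb)."""
    return make_phantom(PhantomSpec(mv_length=24, sb_length=12,
                                    mesh_pitch=0.12))


@pytest.fixture(scope="session")
def gt_y():
    """Analytic Y phantom: straight MV, SB leaving at 60 degrees."""
    return make_phantom(PhantomSpec(mv_length=24, sb_length=12,
                                    angle_a=120, angle_b=60, angle_c=180,
                                    mesh_pitch=0.12))


@pytest.fixture(scope="session")
def zero_noise_recon(gt_small):
    """End-to-end reconstruction of noise-free pullbacks of gt_small."""
    gt = gt_small
    mv = simulate_pullback(gt, "MV", centroid_jitter_mm=0.0, seed=11)
    sb = simulate_pullback(gt, "SB", centroid_jitter_mm=0.0, seed=12)
    config = RunConfig(pitch_mm=0.12)
    lumen, wall, report, framesets = reconstruct_bifurcation(
        gt.backbone, mv, sb, config)
    gt_restricted = gt.mesh_for(
        mv_range=(framesets["MV"].stations[0], framesets["MV"].stations[-1]),
        sb_range=(framesets["SB"].stations[0], framesets["SB"].stations[-1]),
        pitch=0.12)
    return {"gt": gt, "lumen": lumen, "report": report,
            "framesets": framesets, "gt_restricted": gt_restricted,
            "stacks": {"MV": mv, "SB": sb}}


FULL_SPEC = dict(
    mv_radius_profile={"kind": "stenosis", "radius": 1.5, "depth": 0.4,
                       "extent": 12.0, "center": 12.0},
    sb_radius_profile={"kind": "tapered", "r_start": 1.1, "r_end": 0.8,
                       "length": 20.0},
)


@pytest.fixture(scope="session")
def gt_full():
    """Full-size phantom: 40 mm MV coverage -> 200 pullback frames.

    Carries a proximal-MV stenosis and a tapering SB so the serial area
    profiles have real structure to regress against.
    """
    return make_phantom(PhantomSpec(**FULL_SPEC))


@pytest.fixture(scope="session")
def rotation_recovery():
    """Orientation-correction scenario: 200-frame constant-radius elliptical
    pullback (ratio 0.7), walk SD 0.3 deg + one +10 deg jump.

    Constant radius on purpose: where the lumen tapers quickly the smaller
    contour nests inside its neighbour and overlap cannot identify rotation.
    """
    from bifurcate3d.oct_frames import (correct_frame_orientation,
                                        total_pairwise_mismatch)

    gt = make_phantom(PhantomSpec(), build_mesh=False)
    stack = simulate_pullback(gt, "MV", rot_noise=(0.3, 0.0, 0.0),
                              centroid_jitter_mm=0.0, seed=7,
                              forced_jumps={80: 10.0})
    pre = total_pairwise_mismatch(stack)
    corrected = correct_frame_orientation(stack, threshold_fraction=0.0)
    post = total_pairwise_mismatch(corrected)
    return {"gt": gt, "stack": stack, "corrected": corrected,
            "pre": pre, "post": post}


@pytest.fixture(scope="session")
def noisy_recon(gt_full):
    """Noisy full-size reconstruction (walk 0.3 deg, 2% jumps of 8 deg,
    0.3 mm catheter jitter), mirroring the bench validation regime."""
    gt = gt_full
    noise = (0.3, 0.02, 8.0)
    mv = simulate_pullback(gt, "MV", rot_noise=noise, centroid_jitter_mm=0.3,
                           seed=7)
    sb = simulate_pullback(gt, "SB", rot_noise=noise, centroid_jitter_mm=0.3,
                           seed=8)
    config = RunConfig(pitch_mm=0.1)
    lumen, wall, report, framesets = reconstruct_bifurcation(
        gt.backbone, mv, sb, config)
    gt_restricted = gt.mesh_for(
        mv_range=(framesets["MV"].stations[0], framesets["MV"].stations[-1]),
        sb_range=(framesets["SB"].stations[0], framesets["SB"].stations[-1]),
        pitch=0.1)
    return {"gt": gt, "lumen": lumen, "report": report,
            "framesets": framesets, "gt_restricted": gt_restricted}


def ellipse_contour(a=1.5, ratio=0.7, n=72, center=(0.0, 0.0), rot_deg=0.0):
    """Test helper: elliptical contour points."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(th), a * ratio * np.sin(th)])
    if rot_deg:
        c, s = np.cos(np.deg2rad(rot_deg)), np.sin(np.deg2rad(rot_deg))
        pts = pts @ np.array([[c, s], [-s, c]])
    return pts + np.asarray(center)
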