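"""Synthetic bifurcation phantoms with ground truth.

No public dataset carries paired angiographic centerlines and segmented OCT
pullbacks of the same bifurcation, so every pipeline stage is exercised
against analytic phantoms: a Y-shaped lumen built from two (possibly tapered
or stenosed) elliptical tubes whose centerlines meet at a junction with
prescribed bifurcation angles.  The generator returns the exact backbone,
the exact lumen surface, analytic area profiles, and - once a pullback is
simulated - the exact per-frame rotation artifacts that were injected, so
the orientation corrector can be scored against ground truth.

The simulated catheter sits at the contour centroid plus a slowly drifting
eccentricity offset; frame rotation artifacts are a Gaussian random walk plus
sparse jumps (cardiac-motion-like events).  Circular lumens make rotation
unidentifiable, so the default ellipticity is 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import fsolve

from .backbone import (
    BifurcationBackbone,
    Centerline,
    FrameField,
    arc_length_parameterize,
    resample_centerline,
    transport_frames,
)
from .metrics import AngleTriplet
from .oct_frames import Contour, FrameStack
from .surface import LoftRings, TriangleMesh, TubeField, _grid_for, _marching_mesh

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "simulate_pullback"]


# -- radius profiles --------------------------------------------------------

def _profile_function(profile: dict) -> Callable[[np.ndarray], np.ndarray]:
    """Radius (mm) as a function of branch-local arc length.

    Supported kinds: ``constant`` (radius), ``tapered`` (r_start, r_end,
    length), ``stenosis`` (radius, depth, extent, center) where ``depth`` is
    the fractional *area* reduction of the cosine-shaped narrowing.
    """
    kind = profile.get("kind", "constant")
    if kind == "constant":
        r = float(profile["radius"])
        return lambda s: np.full_like(np.asarray(s, float), r)
    if kind == "tapered":
        r0, r1 = float(profile["r_start"]), float(profile["r_end"])
        length = float(profile["length"])
        return lambda s: r0 + (r1 - r0) * np.clip(np.asarray(s, float) / length, 0, 1)
    if kind == "stenosis":
        r = float(profile["radius"])
        depth = float(profile["depth"])
        extent = float(profile["extent"])
        center = float(profile["center"])

        def fn(s):
            s = np.asarray(s, float)
            bump = np.where(np.abs(s - center) <= extent / 2,
                            0.5 * (1 + np.cos(2 * np.pi * (s - center) / extent)),
                            0.0)
            return r * np.sqrt(1.0 - depth * bump)

        return fn
    raise ValueError(f"unknown radius profile kind {kind!r}")


def _profile_min_radius(profile: dict) -> float:
    fn = _profile_function(profile)
    return float(np.min(fn(np.linspace(0, 100, 2001))))


@dataclass
class PhantomSpec:
    """Geometry + noise specification of a synthetic bifurcation.

    Angles are the desired ground-truth bifurcation angles in degrees
    (A: proximal MV vs SB, B: distal MV vs SB, C: proximal vs distal MV);
    they must be realizable by three coplanar unit vectors.  ``carina_offset``
    shifts the junction away from the MV midpoint.  The defaults emulate the
    bench regime of the method: 40 mm MV pullback coverage at 0.2 mm/frame,
    MV radius 1.5 mm, SB radius 1.0 mm, moderately oval lumens.
    """

    mv_length: float = 40.0
    sb_length: float = 20.0
    mv_radius_profile: dict = dc_field(
        default_factory=lambda: {"kind": "constant", "radius": 1.5})
    sb_radius_profile: dict = dc_field(
        default_factory=lambda: {"kind": "constant", "radius": 1.0})
    angle_a: float = 151.0
    angle_b: float = 55.0
    angle_c: float = 154.0
    ellipticity: float = 0.7
    carina_offset: float = 0.0
    fillet_len: float = 1.0
    ostium_blend: float = 2.0
    mesh_pitch: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mv_length < 10 or self.sb_length < 10:
            raise ValueError("branch lengths must be at least 10 mm")
        if not 0 < self.ellipticity <= 1:
            raise ValueError("ellipticity must be in (0, 1]")
        for prof in (self.mv_radius_profile, self.sb_radius_profile):
            if _profile_min_radius(prof) <= 0.3:
                raise ValueError("radii must stay above 0.3 mm")


def _realize_directions(a: float, b: float, c: float):
    """Coplanar unit vectors (p_away, d, s) realizing the angle triple.

    Directions live in the xz-plane with the trunk flow along +z; returns
    None when the triple is not realizable within 0.5 degrees.
    """
    def direction(theta_deg):
        th = np.deg2rad(theta_deg)
        return np.array([np.sin(th), 0.0, np.cos(th)])

    p_away = direction(180.0)           # toward proximal
    theta_d = 180.0 - c                 # angle(p_away, d) == c
    d = direction(theta_d)
    for sign in (+1.0, -1.0):
        theta_s = sign * (180.0 - a)    # angle(p_away, s) == a
        s = direction(theta_s)
        got_b = np.rad2deg(np.arccos(np.clip(np.dot(d, s), -1, 1)))
        if abs(got_b - b) <= 0.5:
            return p_away, d, s
    return None


def _filleted_polyline(p0, corner, p1, fillet_len: float, ds: float = 0.05):
    """Two straight legs joined by a circular fillet with tangent continuity."""
    p0, corner, p1 = (np.asarray(q, float) for q in (p0, corner, p1))
    t_in = corner - p0
    t_in /= np.linalg.norm(t_in)
    t_out = p1 - corner
    t_out /= np.linalg.norm(t_out)
    cosang = np.clip(np.dot(t_in, t_out), -1, 1)
    if cosang > 1 - 1e-12:  # straight through: no fillet needed
        pts = [p0, p1]
        return np.array(pts)
    turn = np.arccos(cosang)
    # tangent offset from the corner so the arc length is ~fillet_len
    radius = fillet_len / turn
    offset = radius * np.tan(turn / 2)
    offset = min(offset, 0.9 * np.linalg.norm(corner - p0),
                 0.9 * np.linalg.norm(p1 - corner))
    a = corner - t_in * offset
    b = corner + t_out * offset
    # arc from a to b: rotate t_in toward t_out about the binormal
    n_steps = max(int(np.ceil(turn * radius / ds)), 4)
    axis = np.cross(t_in, t_out)
    axis /= np.linalg.norm(axis)
    radius_eff = offset / np.tan(turn / 2)
    center = a + radius_eff * np.cross(axis, t_in)
    arc = []
    for t in np.linspace(0, turn, n_steps + 1)[1:-1]:
        rot = _axis_rotation(axis, t)
        arc.append(center + rot @ (a - center))
    pts = np.vstack([[p0], [a], arc, [b], [p1]])
    keep = np.ones(len(pts), bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9
    return pts[keep]


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


@dataclass
class GroundTruth:
    """Exact phantom geometry plus any injected pullback artifacts."""

    spec: PhantomSpec
    backbone: BifurcationBackbone
    lumen_mesh: TriangleMesh
    true_angles: AngleTriplet
    junction: np.ndarray                # 3D junction point of the centerlines
    junction_param_mv: float            # arc length of the junction on the MV
    junction_param_sb: float
    injected_rotations: dict = dc_field(default_factory=dict)
    injected_jitter: dict = dc_field(default_factory=dict)

    # -- analytic queries --------------------------------------------------
    def radius(self, branch: str, s: np.ndarray) -> np.ndarray:
        """Semi-major radius at centerline arc length ``s`` of the branch.

        On the shared trunk (proximal of the junction) the SB centerline
        carries the MV lumen.
        """
        s = np.asarray(s, float)
        mv_fn = _profile_function(self.spec.mv_radius_profile)
        if branch == "MV":
            return mv_fn(s)
        sb_fn = _profile_function(self.spec.sb_radius_profile)
        # smooth trunk -> SB handoff over the ostium (no real pullback shows
        # a radius step between consecutive frames)
        sj = self.junction_param_sb
        half = self.spec.ostium_blend / 2
        t = np.clip((s - (sj - half)) / max(self.spec.ostium_blend, 1e-9), 0, 1)
        w = t * t * (3 - 2 * t)  # smoothstep
        return (1 - w) * mv_fn(s) + w * sb_fn(np.maximum(s - sj, 0.0))

    def analytic_area(self, branch: str, s: np.ndarray) -> np.ndarray:
        """Exact elliptical cross-section area (mm^2) away from the carina."""
        r = self.radius(branch, s)
        return np.pi * r * r * self.spec.ellipticity

    def centerline(self, branch: str) -> Centerline:
        return self.backbone.mv if branch == "MV" else self.backbone.sb

    def carina_param(self, branch: str) -> float:
        return (self.backbone.carina_mv if branch == "MV"
                else self.backbone.carina_sb)

    def mesh_for(self, mv_range: tuple[float, float] | None = None,
                 sb_range: tuple[float, float] | None = None,
                 pitch: float | None = None) -> TriangleMesh:
        """Ground-truth lumen surface restricted to given axial coverage.

        A pullback anchored at the carina generally does not start exactly at
        arc length 0, so a fair surface comparison restricts the truth to the
        imaged segment.  Ranges are (start, end) arc lengths per branch; the
        SB start is never taken proximal of the carina point (proximal-MV
        rule).  Defaults reproduce ``lumen_mesh``.
        """
        ds = 0.1
        pitch = self.spec.mesh_pitch if pitch is None else pitch
        mv_lo, mv_hi = mv_range if mv_range else (0.0, self.backbone.mv.total_length)
        sb_lo, sb_hi = sb_range if sb_range else (0.0, self.backbone.sb.total_length)
        sb_lo = max(sb_lo, self.backbone.carina_sb)
        mv_field = TubeField(_analytic_rings(
            self, "MV", np.arange(mv_lo, mv_hi + 1e-9, ds)))
        sb_field = TubeField(_analytic_rings(
            self, "SB", np.arange(sb_lo, sb_hi + 1e-9, ds)))
        pts = np.vstack([mv_field.meta.rings.reshape(-1, 3),
                         sb_field.meta.rings.reshape(-1, 3)])
        _, axes = _grid_for(pts, pitch)
        mesh = _marching_mesh(lambda p: np.minimum(mv_field.value(p),
                                                   sb_field.value(p)),
                              axes, pitch)
        return TriangleMesh(vertices=mesh.vertices.copy(),
                            faces=mesh.faces.copy())

    def sections(self, branch: str, stations: np.ndarray):
        """Analytic lumen ellipses at the given ascending arc lengths.

        Returns ``(field, points)`` where ``points[i]`` is the (n, 3) world
        ellipse at ``stations[i]`` and ``field`` holds the frames used.
        """
        cl = self.centerline(branch)
        fld = transport_frames(cl, stations=np.asarray(stations, float))
        a = self.radius(branch, fld.stations)
        b = a * self.spec.ellipticity
        theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        pts = (fld.origins[:, None, :]
               + a[:, None, None] * np.cos(theta)[None, :, None] * fld.u[:, None, :]
               + b[:, None, None] * np.sin(theta)[None, :, None] * fld.v[:, None, :])
        return fld, pts


def _analytic_rings(gt_like, branch, stations) -> LoftRings:
    fld, pts = gt_like.sections(branch, stations)
    return LoftRings(rings=pts, stations=fld.stations, origins=fld.origins,
                     u=fld.u, v=fld.v, normals=fld.tangents,
                     branch_label=branch)


def make_phantom(spec: PhantomSpec, build_mesh: bool = True) -> GroundTruth:
    """Build the exact phantom geometry (deterministic; no randomness).

    Centerlines realize the requested angles within 0.5 degrees (straight
    limbs, short tangent-continuous fillet at the junction); the carina
    reference is solved exactly on the ridge where the two tube surfaces
    intersect; the ground-truth lumen surface is the union of the two
    analytic tubes (SB trimmed proximal of its carina point, matching the
    reconstruction's proximal-MV rule) extracted at ``mesh_pitch``.
    """
    dirs = _realize_directions(spec.angle_a, spec.angle_b, spec.angle_c)
    if dirs is None:
        raise ValueError(
            f"angle triple ({spec.angle_a}, {spec.angle_b}, {spec.angle_c}) "
            "is not realizable by coplanar directions")
    p_away, d_hat, s_hat = dirs
    lp = spec.mv_length / 2 + spec.carina_offset
    ld = spec.mv_length - lp
    junction = np.zeros(3)
    p0 = junction + p_away * lp

    mv_pts = _filleted_polyline(p0, junction, junction + d_hat * ld,
                                spec.fillet_len)
    sb_pts = _filleted_polyline(p0, junction, junction + s_hat * spec.sb_length,
                                spec.fillet_len)
    mv = resample_centerline(arc_length_parameterize(
        Centerline(mv_pts, branch_label="MV")))
    sb = resample_centerline(arc_length_parameterize(
        Centerline(sb_pts, branch_label="SB")))

    # junction arc-length parameters (projection of the junction point)
    from .backbone import project_carina
    s_j_mv, _ = project_carina(junction, mv)
    s_j_sb, _ = project_carina(junction, sb)

    # provisional ground truth (no mesh yet) for analytic section queries
    stub = GroundTruth.__new__(GroundTruth)
    stub.spec = spec
    stub.junction = junction
    stub.junction_param_mv = s_j_mv
    stub.junction_param_sb = s_j_sb
    stub.backbone = BifurcationBackbone(mv=mv, sb=sb, carina_ref=junction,
                                        carina_mv=s_j_mv, carina_sb=s_j_sb)

    ds = 0.1
    mv_field = TubeField(_analytic_rings(stub, "MV",
                                         np.arange(0, mv.total_length + 1e-9, ds)))
    sb_field_full = TubeField(_analytic_rings(stub, "SB",
                                              np.arange(0, sb.total_length + 1e-9, ds)))

    carina_ref = _solve_carina(mv_field, sb_field_full, junction, d_hat, s_hat,
                               stub)
    backbone = BifurcationBackbone.from_geometry(mv, sb, carina_ref,
                                                 resample_ds=None)
    stub.backbone = backbone

    true_angles = AngleTriplet(
        angle_a=_deg(p_away, s_hat), angle_b=_deg(d_hat, s_hat),
        angle_c=_deg(p_away, d_hat))
    gt = GroundTruth(spec=spec, backbone=backbone, lumen_mesh=None,
                     true_angles=true_angles, junction=junction,
                     junction_param_mv=s_j_mv, junction_param_sb=s_j_sb)
    if build_mesh:
        # ground-truth surface: union with the SB trimmed at its carina point
        gt.lumen_mesh = gt.mesh_for()
    return gt


def _deg(a, b) -> float:
    return float(np.rad2deg(np.arccos(np.clip(np.dot(a, b), -1, 1))))


def _solve_carina(mv_field, sb_field, junction, d_hat, s_hat, stub):
    """Carina reference: ridge point where the two tube surfaces intersect.

    Solved in the bifurcation plane, in the wedge between the two distal
    directions, as the root of (f_mv, f_sb) = 0.
    """
    e1 = d_hat + s_hat
    e1 /= np.linalg.norm(e1)
    e2 = d_hat - s_hat
    e2 /= np.linalg.norm(e2)
    r0 = float(stub.radius("MV", stub.junction_param_mv))

    def residual(ab):
        p = junction + ab[0] * e1 + ab[1] * e2
        return [mv_field.value(p[None, :])[0], sb_field.value(p[None, :])[0]]

    sol, info, ok, _ = fsolve(residual, x0=[1.5 * r0, 0.0], full_output=True)
    if ok != 1 or np.max(np.abs(info["fvec"])) > 1e-6:
        raise ValueError("failed to locate the carina ridge point")
    return junction + sol[0] * e1 + sol[1] * e2


# ---------------------------------------------------------------------------
# pullback simulation
# ---------------------------------------------------------------------------

def simulate_pullback(
    gt: GroundTruth,
    branch: str = "MV",
    spacing: float = 0.2,
    rot_noise: tuple[float, float, float] = (0.0, 0.0, 0.0),
    centroid_jitter_mm: float = 0.3,
    seed: int | None = None,
    forced_jumps: dict[int, float] | None = None,
    wall_scale: float | None = None,
) -> FrameStack:
    """Simulate a segmented OCT pullback of one branch.

    Frames are the analytic lumen sections along the branch centerline in
    pullback order (distal -> proximal), expressed about a simulated catheter
    center (centroid + slowly drifting jitter) and rotated by an injected
    artifact angle: a Gaussian random walk (``walk_sd_deg`` per frame) plus
    sparse persistent jumps (``jump_prob``, ``jump_sd_deg``), plus any
    ``forced_jumps`` {frame_index: degrees}.  The injected cumulative angles
    are recorded in ``gt.injected_rotations[branch]`` (degrees, pullback
    order); the carina frame and its 2D carina location are annotated from
    the exact geometry.
    """
    walk_sd, jump_prob, jump_sd = rot_noise
    cl = gt.centerline(branch)
    L = cl.total_length
    if spacing <= 0 or spacing > L:
        raise ValueError("spacing must be positive and not exceed the branch length")
    n = int(np.floor(L / spacing)) + 1
    stations_pullback = L - np.arange(n) * spacing     # distal -> proximal
    order = np.argsort(stations_pullback)              # ascending for frames
    fld, world = gt.sections(branch, stations_pullback[order])
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)

    rng = np.random.default_rng(gt.spec.seed if seed is None else seed)
    steps = rng.normal(0.0, walk_sd, n)
    steps[0] = 0.0
    jump_mask = rng.random(n) < jump_prob
    jump_mask[0] = False
    jump_steps = np.where(jump_mask, rng.normal(0.0, jump_sd, n), 0.0)
    alpha = np.cumsum(steps + jump_steps)
    if forced_jumps:
        for k, deg in forced_jumps.items():
            alpha[int(k):] += float(deg)
    raw = rng.normal(0.0, 1.0, (n, 2))
    if centroid_jitter_mm > 0:
        sm = gaussian_filter1d(raw, sigma=10.0, axis=0, mode="nearest")
        rms = np.sqrt(np.mean(np.sum(sm ** 2, axis=1)))
        jitter = sm * (centroid_jitter_mm / rms)
    else:
        jitter = np.zeros((n, 2))

    carina_s = gt.carina_param(branch)
    carina_idx = int(np.argmin(np.abs(stations_pullback - carina_s)))
    carina_ref = gt.backbone.carina_ref

    contours = []
    walls = [] if wall_scale is not None else None
    carina_2d = None
    for j in range(n):
        i = inv[j]
        rel = world[i] - fld.origins[i]
        xy = np.column_stack([rel @ fld.u[i], rel @ fld.v[i]])
        center = xy.mean(axis=0) + jitter[j]
        pts = _rot2(xy - center, alpha[j])
        contours.append(Contour(points=pts))
        if walls is not None:
            wall_xy = xy.mean(axis=0) + wall_scale * (xy - xy.mean(axis=0))
            walls.append(Contour(points=_rot2(wall_xy - center, alpha[j]),
                                 channel="wall"))
        if j == carina_idx:
            crel = carina_ref - fld.origins[i]
            c2 = np.array([crel @ fld.u[i], crel @ fld.v[i]]) - center
            carina_2d = _rot2(c2[None, :], alpha[j])[0]

    gt.injected_rotations[branch] = alpha
    gt.injected_jitter[branch] = jitter
    return FrameStack(contours=contours, spacing=spacing, branch_label=branch,
                      carina_frame_index=carina_idx, carina_point_2d=carina_2d,
                      wall_contours=walls)


def _rot2(pts: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return pts @ np.array([[c, s], [-s, c]])
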