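"""Segmented OCT pullbacks and rotational-artifact correction.

An OCT pullback produces one cross-sectional frame every ``spacing`` mm
(0.2 mm at 5 frames/mm) while the catheter is withdrawn distal -> proximal.
Because acquisition is not ECG gated, cardiac motion rotates individual
frames about the catheter axis.  The corrector exploits two facts: frames can
only rotate about the catheter center (fixed in the image), and consecutive
frames image nearly the same lumen.  Whenever the symmetric-difference area
between a frame and its (already corrected) predecessor exceeds a fraction of
the mean frame area, the frame is rotated on a 0.5-degree grid to minimize
that area, and the correction is propagated to all downstream frames.

All contours live in frame coordinates with the catheter center at the
origin; positive orientation (counter-clockwise) is enforced on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "Contour",
    "FrameStack",
    "package_frames",
    "mismatch_area",
    "correct_frame_orientation",
    "apply_rotation_log",
    "rotate_points",
    "resample_closed",
]


def rotate_points(points: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate 2D points about the origin (catheter center) by ``theta_deg``."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    return np.asarray(points, dtype=float) @ rot.T


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points, uniform in arc length.

    The first output point coincides with the first input vertex; the implicit
    closing edge is included.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, closed.shape[1]))
    for k in range(closed.shape[1]):
        out[:, k] = np.interp(target, s, closed[:, k])
    return out


@dataclass
class Contour:
    """Closed simple polygon in a single OCT frame (catheter center at origin).

    Cleaning on construction: consecutive duplicate vertices (and a repeated
    closing vertex) are dropped, counter-clockwise orientation is enforced,
    and self-intersecting polygons are rejected.
    """

    points: np.ndarray
    channel: str = "lumen"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
        pts = pts[keep]
        if len(pts) < 3:
            raise ValueError("contour needs at least 3 distinct points")
        if _signed_area(pts) < 0:
            pts = pts[::-1].copy()
        if _signed_area(pts) <= 0:
            raise ValueError("contour has non-positive area")
        if not Polygon(pts).is_valid:
            raise ValueError("contour polygon is self-intersecting")
        self.points = pts

    @property
    def area(self) -> float:
        return _signed_area(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(Polygon(self.points).centroid.coords[0])

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def rotated(self, theta_deg: float) -> "Contour":
        """Rigidly rotated copy about the catheter center."""
        return Contour(points=rotate_points(self.points, theta_deg),
                       channel=self.channel)


@dataclass
class FrameStack:
    """One OCT pullback: lumen contours in pullback order (distal -> proximal).

    ``rotation_log`` records the correction angle (degrees) already applied to
    each frame; it starts at zero and is filled by
    :func:`correct_frame_orientation`.
    """

    contours: list[Contour]
    spacing: float = 0.2
    branch_label: str = "MV"
    carina_frame_index: int = 0
    carina_point_2d: np.ndarray = field(default_factory=lambda: np.zeros(2))
    wall_contours: list[Contour] | None = None
    rotation_log: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("frame spacing must be positive")
        n = len(self.contours)
        if n == 0:
            raise ValueError("frame stack is empty")
        if not 0 <= self.carina_frame_index < n:
            raise ValueError(
                f"carina_frame_index {self.carina_frame_index} outside 0..{n - 1}"
            )
        self.carina_point_2d = np.asarray(self.carina_point_2d, dtype=float).reshape(2)
        if self.rotation_log is None:
            self.rotation_log = np.zeros(n)
        self.rotation_log = np.asarray(self.rotation_log, dtype=float)
        if len(self.rotation_log) != n:
            raise ValueError("rotation_log length must equal the frame count")
        if self.wall_contours is not None and len(self.wall_contours) != n:
            raise ValueError("wall_contours length must equal the frame count")
        carina_poly = self.contours[self.carina_frame_index].polygon()
        if carina_poly.distance(Point(self.carina_point_2d)) > 0.5:
            raise ValueError(
                "carina_point_2d lies more than 0.5 mm outside the carina frame lumen"
            )

    @property
    def n_frames(self) -> int:
        return len(self.contours)


def package_frames(stack: FrameStack) -> np.ndarray:
    """Axial position (mm) of each frame along the straight catheter axis."""
    return np.arange(stack.n_frames) * stack.spacing


def _polygon_cached(contour: Contour) -> Polygon:
    poly = contour.polygon()
    if not poly.is_valid:
        raise ValueError("contour polygon is self-intersecting")
    return poly


def mismatch_area(a: Contour, b: Contour, theta_deg: float = 0.0) -> float:
    """Symmetric-difference area (mm^2) between ``a`` and ``b`` rotated by theta.

    Zero iff the rotated polygons coincide; this is the objective the
    orientation corrector minimizes ("overlapping outside areas").
    """
    pa = _polygon_cached(a)
    pb = _polygon_cached(b.rotated(theta_deg) if theta_deg else b)
    return float(pa.symmetric_difference(pb).area)


def _candidate_grid(max_range_deg: float, step: float = 0.5) -> np.ndarray:
    """Candidate rotations ordered by (|delta|, delta): 0, -0.5, +0.5, ..."""
    k = int(round(max_range_deg / step))
    mags = np.repeat(np.arange(1, k + 1) * step, 2)
    signs = np.tile([-1.0, 1.0], k)
    return np.concatenate([[0.0], mags * signs])


def _batch_mismatch(poly_a: Polygon, pts_b: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Vectorized symmetric-difference areas of ``poly_a`` vs rotated ``pts_b``."""
    th = np.deg2rad(deltas)
    c, s = np.cos(th), np.sin(th)
    rot = np.empty((len(deltas), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    rotated = np.einsum("kij,nj->kni", rot, pts_b)
    polys = shapely.polygons(rotated)
    return shapely.area(shapely.symmetric_difference(poly_a, polys))


def correct_frame_orientation(
    stack: FrameStack,
    threshold_fraction: float = 0.10,
    max_range_deg: float = 180.0,
    step_deg: float = 0.5,
) -> FrameStack:
    """Correct per-frame rotational misalignment by overlap minimization.

    Sweeps distal -> proximal over successive pairs.  If the mismatch between
    the corrected frame ``i`` and the (cumulatively pre-rotated) frame ``i+1``
    exceeds ``threshold_fraction`` times the mean of the two frame areas, the
    rotation on the +-``max_range_deg`` grid (``step_deg`` increments) that
    minimizes the mismatch is applied to frame ``i+1`` and, cumulatively, to
    every frame downstream.  Ties break toward the smallest |rotation|, so a
    stack of rotationally symmetric frames is left untouched.  Frame 0 (most
    distal) anchors the chain and is never rotated; the remaining global roll
    is fixed later at the carina.

    Returns a new stack with rotated lumen contours (and carina annotation)
    and the applied angles in ``rotation_log``.  Wall contours are *not*
    rotated here; use :func:`apply_rotation_log`.
    """
    if stack.n_frames < 2:
        raise ValueError("orientation correction needs at least 2 frames")
    deltas = _candidate_grid(max_range_deg, step_deg)
    contours = list(stack.contours)
    log = stack.rotation_log.astype(float).copy()
    cum = 0.0
    for i in range(stack.n_frames - 1):
        nxt = contours[i + 1].rotated(cum) if cum else contours[i + 1]
        pa = _polygon_cached(contours[i])
        m0 = float(pa.symmetric_difference(_polygon_cached(nxt)).area)
        gate = threshold_fraction * 0.5 * (contours[i].area + nxt.area)
        if m0 > gate:
            areas = _batch_mismatch(pa, nxt.points, deltas)
            # smallest-|rotation| tie-break: candidates are ordered by
            # (|delta|, delta); near-ties (e.g. nested contours, circles)
            # must resolve to the first, not a floating-noise argmin
            m_best = float(areas.min())
            tol = 1e-9 * max(m_best, 1.0)
            best = float(deltas[int(np.nonzero(areas <= m_best + tol)[0][0])])
            cum += best
            nxt = contours[i + 1].rotated(cum)
        contours[i + 1] = nxt
        log[i + 1] += cum
    carina_pt = rotate_points(stack.carina_point_2d[None, :],
                              log[stack.carina_frame_index]
                              - stack.rotation_log[stack.carina_frame_index])[0]
    return replace(stack, contours=contours, rotation_log=log,
                   carina_point_2d=carina_pt)


def apply_rotation_log(stack: FrameStack, channel: str = "wall") -> FrameStack:
    """Rotate the wall contours by each frame's logged correction angle.

    The vessel wall is reconstructed with the same frame-orientation
    correction and carina rotation as the lumen, so the wall channel simply
    replays the lumen's rotation log.  The lumen contours are untouched.
    """
    if channel != "wall":
        raise ValueError("only the wall channel replays the rotation log")
    if stack.wall_contours is None:
        raise ValueError("stack has no wall channel")
    rotated = [w.rotated(ang) if ang else w
               for w, ang in zip(stack.wall_contours, stack.rotation_log)]
    return replace(stack, wall_contours=rotated)


def total_pairwise_mismatch(stack: FrameStack) -> float:
    """Sum of symmetric-difference areas over all successive frame pairs."""
    return float(sum(mismatch_area(a, b)
                     for a, b in zip(stack.contours[:-1], stack.contours[1:])))
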