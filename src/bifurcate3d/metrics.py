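"""Validation metrics and agreement statistics.

Method comparison between a reconstructed bifurcation and a reference model
(e.g. a micro-CT gold standard) uses three morphometric quantities computed
on cross-sections taken every 2 mm along the lumen:

* lumen area, z-score normalized per series because imaging in saline causes
  a consistent scale offset between modalities;
* lumen shape, the ratio of the longest chord of the section boundary
  (distance X) to the maximal extent perpendicular to it (distance Y), Y/X;
* the three bifurcation angles: A between proximal MV and SB, B between
  distal MV and SB, C between distal and proximal MV, each from
  tangent-averaged limb directions around the carina.

Agreement is summarized by ordinary least squares regression (r^2 as squared
Pearson correlation) and Bland-Altman limits of agreement
(mean difference +- 1.96 sample SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh.intersections
from scipy import stats
from shapely.geometry import Point
import shapely
from shapely.ops import polygonize, unary_union
import shapely.geometry as sgeom

from .backbone import BifurcationBackbone, Centerline
from .oct_frames import resample_closed
from .surface import TriangleMesh

__all__ = [
    "AreaSeries",
    "ShapeMeasure",
    "AngleTriplet",
    "AgreementReport",
    "cross_section_areas",
    "cross_section_polygon",
    "zscore",
    "lumen_shape",
    "bifurcation_angles",
    "bland_altman",
    "linear_regress",
    "compare_area_series",
]


@dataclass
class AreaSeries:
    """Serial lumen areas along one branch (positions from the proximal end)."""

    positions: np.ndarray  # mm, strictly increasing
    areas: np.ndarray      # mm^2, positive
    branch_label: str = "MV"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")


@dataclass
class ShapeMeasure:
    """Lumen-shape marker: Y/X ratio of perpendicular maximal extents."""

    x_dist: float
    y_dist: float

    def __post_init__(self) -> None:
        if not self.x_dist >= self.y_dist > 0:
            raise ValueError("require x_dist >= y_dist > 0")

    @property
    def ratio(self) -> float:
        return self.y_dist / self.x_dist


@dataclass
class AngleTriplet:
    """Bifurcation angles in degrees: A (prox MV-SB), B (dist MV-SB), C (MV)."""

    angle_a: float
    angle_b: float
    angle_c: float

    def __post_init__(self) -> None:
        for name in ("angle_a", "angle_b", "angle_c"):
            val = getattr(self, name)
            if not 0.0 < val <= 180.0:
                raise ValueError(f"{name}={val} outside (0, 180]")

    def as_array(self) -> np.ndarray:
        return np.array([self.angle_a, self.angle_b, self.angle_c])


@dataclass
class AgreementReport:
    """Regression + Bland-Altman summary of one method comparison."""

    slope: float
    intercept: float
    r_squared: float
    mean_diff: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")
        sd = (self.loa_high - self.loa_low) / (2 * 1.96)
        if not (np.isclose(self.loa_low, self.mean_diff - 1.96 * sd)
                and np.isclose(self.loa_high, self.mean_diff + 1.96 * sd)):
            raise ValueError("limits of agreement inconsistent with mean_diff")


# ---------------------------------------------------------------------------
# cross sections
# ---------------------------------------------------------------------------

def cross_section_polygon(
    mesh: TriangleMesh, origin: np.ndarray, normal: np.ndarray,
    keep_point: np.ndarray | None = None,
):
    """Planar section of a mesh, keeping the loop containing ``keep_point``.

    Returns a shapely polygon in an in-plane 2D basis, or ``None`` when the
    plane misses the mesh or no loop contains the point.
    """
    tm = mesh.to_trimesh()
    segments = trimesh.intersections.mesh_plane(tm, plane_normal=normal,
                                                plane_origin=origin)
    if len(segments) == 0:
        return None
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    seg2 = np.einsum("sij,kj->sik", segments - origin, np.stack([u, v]))
    lines = [sgeom.LineString(s) for s in seg2 if np.linalg.norm(s[0] - s[1]) > 1e-12]
    merged = unary_union(sgeom.MultiLineString(lines))
    # snap endpoints so the segment soup nodes into closed rings
    polys = list(polygonize(shapely.set_precision(merged, 1e-9)))
    if not polys:
        return None
    if keep_point is None:
        return max(polys, key=lambda p: p.area)
    kp = np.asarray(keep_point, float) - origin
    p2 = Point(np.dot(kp, u), np.dot(kp, v))
    containing = [p for p in polys if p.contains(p2)]
    if not containing:
        return None
    return min(containing, key=lambda p: p.area)


def cross_section_areas(
    mesh: TriangleMesh,
    centerline: Centerline,
    step: float = 2.0,
    s_range: tuple[float, float] | None = None,
) -> AreaSeries:
    """Serial cross-section areas every ``step`` mm along the centerline.

    The sectioning plane at each station passes through the centerline point
    with the local tangent as normal; only the connected component containing
    the centerline point is kept.  An empty section (centerline outside the
    mesh) raises, naming the position.
    """
    cl = centerline
    cl._require_param()
    lo, hi = s_range if s_range is not None else (0.0, cl.total_length)
    positions = list(np.arange(lo, hi + 1e-9, step))
    if positions and hi - positions[-1] > 1e-6:
        positions.append(hi)  # last interval may be shorter
    if not positions:
        positions = [lo]
    areas = []
    for s in positions:
        p = cl.point_at(s)
        t = cl.tangent_at(s)
        poly = cross_section_polygon(mesh, p, t, keep_point=p)
        if poly is None:
            raise ValueError(f"empty cross-section at position {s:.3f} mm "
                             "(centerline outside mesh)")
        areas.append(poly.area)
    return AreaSeries(positions=np.asarray(positions), areas=np.asarray(areas),
                      branch_label=cl.branch_label)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score normalization (value - mean) / sample SD.

    Removes the consistent between-modality scale offset so area profiles can
    be regressed against each other.  Sample SD (ddof=1); a constant series
    is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series has no z-score")
    return (x - x.mean()) / sd


def lumen_shape(contour: np.ndarray, n_boundary: int = 512,
                y_mode: str = "extent") -> ShapeMeasure:
    """Lumen-shape measure of a planar cross-section polygon.

    distance X is the maximum distance between boundary points (the longest
    chord); distance Y is, by default, the extent of the boundary projected
    onto the direction perpendicular to the X chord (equal to the maximal
    perpendicular chord for convex sections and well defined for slightly
    concave OCT contours).  ``y_mode="chord"`` instead takes the longest
    boundary chord perpendicular (within 1e-6) to X.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (n>=3, 2) polygon")
    if abs(_poly_area(pts)) < 1e-12:
        raise ValueError("degenerate contour with zero area")
    n = max(n_boundary, 2 * len(pts))
    bnd = resample_closed(pts, n)
    # longest chord between boundary points (brute force, vectorized)
    d2 = np.sum((bnd[:, None, :] - bnd[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    x_dist = float(np.sqrt(d2[i, j]))
    ex = (bnd[j] - bnd[i]) / x_dist
    perp = np.array([-ex[1], ex[0]])
    proj = bnd @ perp
    if y_mode == "extent":
        y_dist = float(proj.max() - proj.min())
    elif y_mode == "chord":
        along = bnd @ ex
        # longest pair with (near-)equal projection on the X direction
        da = np.abs(along[:, None] - along[None, :])
        mask = da < x_dist * 1e-3
        dp = np.abs(proj[:, None] - proj[None, :])
        y_dist = float((dp * mask).max())
    else:
        raise ValueError(f"unknown y_mode {y_mode!r}")
    y_dist = min(y_dist, x_dist)  # guard floating noise on circles
    return ShapeMeasure(x_dist=x_dist, y_dist=y_dist)


def _poly_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _limb_direction(cl: Centerline, s0: float, s1: float, window: float,
                    clearance: float) -> np.ndarray:
    """Normalized mean tangent from s0 toward s1 (direction away from carina).

    The first ``clearance`` mm after the carina parameter are skipped so the
    bifurcation core (where the two branch centerlines converge and bend)
    does not contaminate the limb direction.
    """
    length = abs(s1 - s0)
    if length < 1.0:
        raise ValueError("limb shorter than 1 mm")
    clearance = min(clearance, max(length - window, 0.0))
    start = s0 + np.sign(s1 - s0) * clearance
    w = min(window, abs(s1 - start))
    samples = np.linspace(start, start + np.sign(s1 - s0) * w,
                          max(int(w / 0.1), 5))
    tans = cl.tangent_at(samples) * np.sign(s1 - s0)
    mean = tans.mean(axis=0)
    return mean / np.linalg.norm(mean)


def bifurcation_angles(backbone: BifurcationBackbone,
                       window: float = 5.0,
                       carina_clearance: float | None = None) -> AngleTriplet:
    """Bifurcation angles from tangent-averaged limb directions.

    Pointwise tangents at the carina are noise dominated, so each limb
    direction is the normalized mean of centerline tangents over ``window``
    mm of its limb, pointing away from the carina: p (MV proximal), d (MV
    distal), s (SB distal).  The carina point itself sits distal to the spot
    where the two branch centerlines converge, so each window starts after a
    carina clearance (default: twice the distance from the carina reference
    to the branch centerline, i.e. roughly one lumen diameter) to keep the
    junction bend out of the limb direction.
    """
    mv, sb = backbone.mv, backbone.sb
    if carina_clearance is None:
        clear_mv = 2.0 * float(np.linalg.norm(
            backbone.carina_ref - mv.point_at(backbone.carina_mv)))
        clear_sb = 2.0 * float(np.linalg.norm(
            backbone.carina_ref - sb.point_at(backbone.carina_sb)))
    else:
        clear_mv = clear_sb = carina_clearance
    p = _limb_direction(mv, backbone.carina_mv, 0.0, window, clear_mv)
    d = _limb_direction(mv, backbone.carina_mv, mv.total_length, window, clear_mv)
    s = _limb_direction(sb, backbone.carina_sb, sb.total_length, window, clear_sb)

    def ang(a, b):
        return float(np.rad2deg(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))))

    return AngleTriplet(angle_a=ang(p, s), angle_b=ang(d, s), angle_c=ang(p, d))


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Bland-Altman agreement: mean difference and mean +- 1.96 sample SD.

    ``pairs`` is an (n, 2) array of (method1, method2) values; differences are
    method1 - method2.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("bland_altman needs at least 2 (method1, method2) pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def linear_regress(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares y on x: (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("regression needs n >= 3 paired values")
    if np.var(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def agreement_report(test: np.ndarray, reference: np.ndarray) -> AgreementReport:
    """Full agreement summary; regression uses the reference as response."""
    slope, intercept, r2 = linear_regress(test, reference)
    mean, (lo, hi) = bland_altman(np.column_stack([test, reference]))
    return AgreementReport(slope=slope, intercept=intercept, r_squared=r2,
                           mean_diff=mean, loa_low=lo, loa_high=hi,
                           n=len(np.asarray(test)))


def compare_area_series(a: AreaSeries, b: AreaSeries) -> AgreementReport:
    """Agreement of two z-score normalized area profiles on shared positions."""
    if len(a.positions) != len(b.positions) or not np.allclose(
            a.positions, b.positions):
        raise ValueError("area series must share sampling positions")
    return agreement_report(zscore(a.areas), zscore(b.areas))
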