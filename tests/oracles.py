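"""Independent reference computations used to check the implementation.

Everything here is deliberately written from first principles (no shapely,
no package geometry code) so tests compare two independent routes.
"""

from __future__ import annotations

import numpy as np


# -- convex polygon clipping -------------------------------------------------

def shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def clip_convex(subject: np.ndarray, clipper: np.ndarray) -> np.ndarray:
    """Sutherland-Hodgman clipping of a polygon by a convex clipper (CCW)."""
    output = [tuple(p) for p in subject]
    m = len(clipper)
    for i in range(m):
        a, b = clipper[i], clipper[(i + 1) % m]
        edge = b - a
        if not output:
            break
        inp = output
        output = []
        for j in range(len(inp)):
            cur = np.array(inp[j])
            prv = np.array(inp[j - 1])
            cur_in = _cross2(edge, cur - a) >= 0
            prv_in = _cross2(edge, prv - a) >= 0
            if cur_in:
                if not prv_in:
                    output.append(tuple(_intersect(prv, cur, a, b)))
                output.append(tuple(cur))
            elif prv_in:
                output.append(tuple(_intersect(prv, cur, a, b)))
    return np.array(output) if output else np.empty((0, 2))


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _intersect(p, q, a, b):
    d1 = q - p
    d2 = b - a
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    t = ((a[0] - p[0]) * d2[1] - (a[1] - p[1]) * d2[0]) / denom
    return p + t * d1


def symdiff_area_convex(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric-difference area of two convex CCW polygons."""
    inter = clip_convex(a, b)
    ai = shoelace_area(inter) if len(inter) >= 3 else 0.0
    return shoelace_area(a) + shoelace_area(b) - 2.0 * ai


def rot2(pts: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return pts @ np.array([[c, s], [-s, c]])


def random_convex_polygon(rng: np.random.Generator, n: int = 10,
                          r_lo: float = 0.5, r_hi: float = 2.0) -> np.ndarray:
    """Random convex CCW polygon around the origin (polar hull construction)."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(r_lo, r_hi, n)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    # convex hull via gift wrapping on few points
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return pts[hull.vertices]


# -- curves ------------------------------------------------------------------

def parallel_transport_u(points: np.ndarray, u0: np.ndarray) -> np.ndarray:
    """Discrete parallel transport of an initial normal along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    u = u0 - np.dot(u0, tangents[0]) * tangents[0]
    u /= np.linalg.norm(u)
    for t in tangents[1:]:
        u = u - np.dot(u, t) * t
        u /= np.linalg.norm(u)
    return u


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Closed-form OLS slope/intercept/r^2 via the normal equations."""
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return float(beta[0]), float(beta[1]), 1.0 - ss_res / ss_tot
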