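"""Fusion of corrected OCT frames with the angiographic backbone.

Each corrected frame is positioned perpendicular to its branch centerline:
the carina frame sits exactly at the branch's carina point (A on the MV, B on
the SB) and every other frame at the known pullback distance from it, walking
along arc length.  The pullback runs distal -> proximal while centerlines are
stored proximal -> distal, so a frame ``j`` frames after the carina frame
sits ``j * spacing`` mm more proximal (smaller arc length).  Frames are
embedded so the centerline passes through the contour centroid (the catheter
is generally eccentric inside the lumen).

A single rigid in-plane rotation, shared by all frames, is then chosen so
that the carina frame's direction reference (catheter center -> annotated 2D
carina location) points at the 3D carina reference point C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon

from .backbone import Centerline
from .backbone import transport_frames as _transport_frames
from .oct_frames import Contour, FrameStack, correct_frame_orientation, rotate_points

__all__ = ["OrientedFrame", "OrientedFrameSet", "place_frames", "carina_align",
           "fuse_branch"]

log = logging.getLogger(__name__)


@dataclass
class OrientedFrame:
    """One OCT frame embedded in 3D.

    ``contour2d`` holds the corrected in-plane lumen polygon in catheter
    coordinates (catheter center at the 2D origin); embedding re-centres it by
    its area centroid so the centerline pierces the lumen centroid.
    """

    station: float              # arc length on the branch centerline (mm)
    origin: np.ndarray          # (3,) centerline point
    u: np.ndarray               # (3,) in-plane basis, maps frame +x
    v: np.ndarray               # (3,) in-plane basis, maps frame +y
    normal: np.ndarray          # (3,) centerline tangent
    contour2d: np.ndarray       # (n, 2) lumen polygon, catheter coords
    pullback_index: int         # frame index in the original stack

    @property
    def centroid2d(self) -> np.ndarray:
        return np.asarray(Polygon(self.contour2d).centroid.coords[0])

    def embed(self, points2d: np.ndarray) -> np.ndarray:
        """Map catheter-frame 2D points into 3D (centroid-centred)."""
        rel = np.asarray(points2d, dtype=float) - self.centroid2d
        return self.origin + rel[:, :1] * self.u + rel[:, 1:2] * self.v

    @property
    def contour3d(self) -> np.ndarray:
        return self.embed(self.contour2d)


@dataclass
class OrientedFrameSet:
    """All embedded frames of one branch, ordered proximal -> distal."""

    frames: list[OrientedFrame]
    branch_label: str
    carina_index: int           # index into ``frames`` of the carina frame
    carina_point_2d: np.ndarray  # annotated carina location (catheter coords)
    spacing: float
    applied_phi_deg: float = 0.0
    dropped_proximal: int = 0
    dropped_distal: int = 0
    wall2d: list[np.ndarray] | None = None  # wall contours, same transforms

    @property
    def stations(self) -> np.ndarray:
        return np.array([f.station for f in self.frames])

    @property
    def carina_frame(self) -> OrientedFrame:
        return self.frames[self.carina_index]

    def rings(self, channel: str = "lumen") -> list[np.ndarray]:
        """Embedded 3D contour rings, proximal -> distal."""
        if channel == "lumen":
            return [f.contour3d for f in self.frames]
        if channel == "wall":
            if self.wall2d is None:
                raise ValueError("frame set has no wall channel")
            return [f.embed(w) for f, w in zip(self.frames, self.wall2d)]
        raise ValueError(f"unknown channel {channel!r}")


def place_frames(
    stack: FrameStack,
    centerline: Centerline,
    carina_param: float,
) -> OrientedFrameSet:
    """Position corrected frames perpendicular to the branch centerline.

    Frame ``k`` (the carina frame) lands at arc length ``carina_param``;
    frame ``j`` at ``carina_param + (k - j) * spacing``.  Frames whose
    required station falls outside the centerline are dropped (no backbone
    exists there) with a logged count.  Bases come from the
    rotation-minimizing frame field, so the embedding adds no twist.
    """
    cl = centerline
    cl._require_param()
    if not 0.0 <= carina_param <= cl.total_length:
        raise ValueError("carina parameter outside centerline range")
    k = stack.carina_frame_index
    j = np.arange(stack.n_frames)
    stations = carina_param + (k - j) * stack.spacing
    inside = (stations >= -1e-9) & (stations <= cl.total_length + 1e-9)
    dropped_distal = int(np.sum(~inside[: k + 1]))
    dropped_proximal = int(np.sum(~inside[k + 1:]))
    if dropped_proximal or dropped_distal:
        log.info("dropped %d proximal and %d distal frames outside the %s "
                 "centerline", dropped_proximal, dropped_distal,
                 stack.branch_label)
    if not inside[k]:  # pragma: no cover - excluded by the range check above
        raise ValueError("carina frame falls outside the centerline")

    keep = np.nonzero(inside)[0]
    s_keep = np.clip(stations[keep], 0.0, cl.total_length)
    order = np.argsort(s_keep)  # proximal -> distal
    s_sorted = s_keep[order]
    field = _transport_frames(cl, stations=s_sorted)

    frames = []
    for idx, (jj, s) in enumerate(zip(keep[order], s_sorted)):
        frames.append(OrientedFrame(
            station=float(s),
            origin=field.origins[idx],
            u=field.u[idx],
            v=field.v[idx],
            normal=field.tangents[idx],
            contour2d=stack.contours[jj].points.copy(),
            pullback_index=int(jj),
        ))
    carina_index = int(np.nonzero(keep[order] == k)[0][0])
    wall2d = None
    if stack.wall_contours is not None:
        wall2d = [stack.wall_contours[jj].points.copy() for jj in keep[order]]
    return OrientedFrameSet(
        frames=frames,
        branch_label=stack.branch_label,
        carina_index=carina_index,
        carina_point_2d=stack.carina_point_2d.copy(),
        spacing=stack.spacing,
        dropped_proximal=dropped_proximal,
        dropped_distal=dropped_distal,
        wall2d=wall2d,
    )


def _rotate_set(frameset: OrientedFrameSet, phi_deg: float) -> OrientedFrameSet:
    """Rotate every frame's in-plane content rigidly by ``phi_deg``."""
    frames = [replace(f, contour2d=rotate_points(f.contour2d, phi_deg))
              for f in frameset.frames]
    wall2d = None
    if frameset.wall2d is not None:
        wall2d = [rotate_points(w, phi_deg) for w in frameset.wall2d]
    return replace(
        frameset,
        frames=frames,
        wall2d=wall2d,
        carina_point_2d=rotate_points(frameset.carina_point_2d[None, :], phi_deg)[0],
        applied_phi_deg=frameset.applied_phi_deg + phi_deg,
    )


def carina_align(
    frameset: OrientedFrameSet,
    carina_ref: np.ndarray,
) -> OrientedFrameSet:
    """Rotate all frames rigidly so the carina direction hits the reference C.

    The direction reference is the in-plane vector from the catheter center to
    the annotated 2D carina location in the carina frame; the target is the
    orthogonal projection of ``carina_ref - origin`` onto the carina frame's
    plane (a rotation about the frame normal can only align in-plane
    directions).  The same angle is applied to every frame, so relative
    orientations are untouched.
    """
    cf = frameset.carina_frame
    d2 = np.asarray(frameset.carina_point_2d, dtype=float)
    if np.linalg.norm(d2) < 1e-9:
        raise ValueError("carina annotation coincides with the catheter center")
    target3 = np.asarray(carina_ref, dtype=float) - cf.origin
    target3 = target3 - np.dot(target3, cf.normal) * cf.normal
    if np.linalg.norm(target3) < 1e-6:
        raise ValueError("carina reference lies on the catheter axis (degenerate)")
    # both directions expressed in the (u, v) plane
    t2 = np.array([np.dot(target3, cf.u), np.dot(target3, cf.v)])
    phi = np.rad2deg(np.arctan2(t2[1], t2[0]) - np.arctan2(d2[1], d2[0]))
    phi = (phi + 180.0) % 360.0 - 180.0
    return _rotate_set(frameset, float(phi))


def fuse_branch(
    stack: FrameStack,
    centerline: Centerline,
    carina_param: float,
    carina_ref: np.ndarray,
    threshold_fraction: float = 0.10,
    max_range_deg: float = 180.0,
) -> OrientedFrameSet:
    """Full per-branch fusion: correct -> place -> carina-align."""
    corrected = correct_frame_orientation(
        stack, threshold_fraction=threshold_fraction, max_range_deg=max_range_deg
    )
    placed = place_frames(corrected, centerline, carina_param)
    return carina_align(placed, carina_ref)
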