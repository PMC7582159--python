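"""File formats: centerline CSV/VTK polylines, contour bundles, meshes.

Conventions (declared in the metadata JSON and validated on load): units mm,
right-handed coordinates, centerlines ordered proximal -> distal, pullback
frames stored distal -> proximal, comma-separated UTF-8 CSV with mandatory
headers and '.' decimal separator.  Readers reject rather than coerce;
writers are bit-stable (write -> read -> write reproduces the bytes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .backbone import BifurcationBackbone, Centerline, arc_length_parameterize
from .oct_frames import Contour, FrameStack
from .surface import TriangleMesh

__all__ = [
    "read_centerline", "write_centerline_csv", "write_centerline_vtk",
    "read_contour_stack", "write_contour_stack",
    "read_bundle", "write_bundle",
    "read_mesh", "write_mesh",
]

_FLOAT_FMT = "%.10g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

def read_centerline(path: str | Path, branch_label: str = "MV") -> Centerline:
    """Read a centerline from CSV (x_mm,y_mm,z_mm) or VTK polyline file."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        pts = _read_centerline_csv(path)
    elif suffix == ".vtk":
        pts = _read_centerline_vtk_legacy(path)
    elif suffix == ".vtp":
        pts = _read_centerline_vtp(path)
    else:
        raise ValueError(f"{path}: unsupported centerline format {suffix!r}")
    return arc_length_parameterize(Centerline(pts, branch_label=branch_label))


def _read_centerline_csv(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    required = ["x_mm", "y_mm", "z_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df[required].to_numpy(dtype=float)


def _read_centerline_vtk_legacy(path: Path) -> np.ndarray:
    """Minimal legacy-ASCII VTK reader: POINTS + first LINES cell."""
    tokens = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 2 or "vtk" not in lines[0].lower():
        raise ValueError(f"{path}: not a VTK legacy file")
    for ln in lines:
        tokens.extend(ln.split())
    tokens_l = [t.lower() for t in tokens]
    if "points" not in tokens_l:
        raise ValueError(f"{path}: no POINTS section")
    i = tokens_l.index("points")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
    if "lines" not in tokens_l:
        raise ValueError(f"{path}: no LINES section")
    j = tokens_l.index("lines")
    k = j + 3
    n_in_cell = int(tokens[k])
    idx = np.array(tokens[k + 1:k + 1 + n_in_cell], dtype=int)
    return coords[idx]


def _read_centerline_vtp(path: Path) -> np.ndarray:
    """Minimal XML PolyData (ascii) reader: Points + first line cell."""
    from lxml import etree

    tree = etree.parse(str(path))
    pts_el = tree.find(".//Points/DataArray")
    if pts_el is None or pts_el.get("format", "ascii") != "ascii":
        raise ValueError(f"{path}: need an ascii Points DataArray")
    coords = np.fromstring(pts_el.text, sep=" ").reshape(-1, 3)
    conn = tree.find(".//Lines/DataArray[@Name='connectivity']")
    offs = tree.find(".//Lines/DataArray[@Name='offsets']")
    if conn is None or offs is None:
        raise ValueError(f"{path}: no Lines connectivity")
    connectivity = np.fromstring(conn.text, sep=" ").astype(int)
    offsets = np.fromstring(offs.text, sep=" ").astype(int)
    return coords[connectivity[: offsets[0]]]


def write_centerline_csv(centerline: Centerline, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("x_mm,y_mm,z_mm\n")
        for p in centerline.points:
            fh.write(",".join(_fmt(v) for v in p) + "\n")


def write_centerline_vtk(centerline: Centerline, path: str | Path) -> None:
    pts = centerline.points
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncenterline\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(" ".join(_fmt(v) for v in p) + "\n")
        fh.write(f"LINES 1 {len(pts) + 1}\n")
        fh.write(" ".join([str(len(pts))] + [str(i) for i in range(len(pts))])
                 + "\n")


# ---------------------------------------------------------------------------
# contour stacks
# ---------------------------------------------------------------------------

def write_contour_stack(stack: FrameStack, csv_path: str | Path,
                        meta_path: str | Path) -> None:
    """Write contours CSV + metadata JSON (layout mirrored by the reader)."""
    with open(csv_path, "w", newline="") as fh:
        fh.write("branch,frame_index,channel,point_index,x_mm,y_mm\n")
        channels = [("lumen", stack.contours)]
        if stack.wall_contours is not None:
            channels.append(("wall", stack.wall_contours))
        for channel, contours in channels:
            for fi, contour in enumerate(contours):
                for pi, (x, y) in enumerate(contour.points):
                    fh.write(f"{stack.branch_label},{fi},{channel},{pi},"
                             f"{_fmt(x)},{_fmt(y)}\n")
    meta = {
        "branch": stack.branch_label,
        "spacing_mm": stack.spacing,
        "carina_frame_index": int(stack.carina_frame_index),
        "carina_point_2d": [float(v) for v in stack.carina_point_2d],
        "units": "mm",
        "frame_order": "distal_to_proximal",
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_contour_stack(csv_path: str | Path, meta_path: str | Path) -> FrameStack:
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("units", "mm") != "mm":
        raise ValueError(f"{meta_path}: unit mismatch, expected mm")
    df = pd.read_csv(csv_path)
    required = ["branch", "frame_index", "channel", "point_index", "x_mm", "y_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing column(s) {missing}")

    def collect(channel: str) -> list[Contour] | None:
        sub = df[df.channel == channel]
        if sub.empty:
            return None
        frames = sorted(sub.frame_index.unique())
        if frames != list(range(len(frames))):
            raise ValueError(f"{csv_path}: non-contiguous frame indices for "
                             f"channel {channel!r}")
        contours = []
        for fi in frames:
            rows = sub[sub.frame_index == fi].sort_values("point_index")
            pts = rows[["x_mm", "y_mm"]].to_numpy(dtype=float)
            try:
                contours.append(Contour(points=pts, channel=channel))
            except ValueError as exc:
                raise ValueError(f"{csv_path}: frame {fi} ({channel}): {exc}")
        return contours

    lumen = collect("lumen")
    if lumen is None:
        raise ValueError(f"{csv_path}: no lumen contours")
    return FrameStack(
        contours=lumen,
        wall_contours=collect("wall"),
        spacing=float(meta["spacing_mm"]),
        branch_label=str(meta["branch"]),
        carina_frame_index=int(meta["carina_frame_index"]),
        carina_point_2d=np.asarray(meta["carina_point_2d"], dtype=float),
    )


# ---------------------------------------------------------------------------
# input bundle
# ---------------------------------------------------------------------------

def write_bundle(dirpath: str | Path, backbone: BifurcationBackbone,
                 stack_mv: FrameStack, stack_sb: FrameStack) -> None:
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    write_centerline_csv(backbone.mv, d / "mv_centerline.csv")
    write_centerline_csv(backbone.sb, d / "sb_centerline.csv")
    with open(d / "backbone.json", "w") as fh:
        json.dump({
            "mv_path": "mv_centerline.csv",
            "sb_path": "sb_centerline.csv",
            "carina_ref": [float(v) for v in backbone.carina_ref],
            "units": "mm",
        }, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_contour_stack(stack_mv, d / "mv_contours.csv", d / "mv_meta.json")
    write_contour_stack(stack_sb, d / "sb_contours.csv", d / "sb_meta.json")


def read_bundle(dirpath: str | Path):
    """Load a bundle directory -> (BifurcationBackbone, FrameStack MV, SB)."""
    d = Path(dirpath)
    cfg_path = d / "backbone.json"
    if not cfg_path.exists():
        raise ValueError(f"{cfg_path}: missing backbone config")
    with open(cfg_path) as fh:
        cfg = json.load(fh)
    for key in ("mv_path", "sb_path", "carina_ref"):
        if key not in cfg:
            raise ValueError(f"{cfg_path}: missing field {key!r}")
    mv = read_centerline(d / cfg["mv_path"], branch_label="MV")
    sb = read_centerline(d / cfg["sb_path"], branch_label="SB")
    backbone = BifurcationBackbone.from_geometry(mv, sb, cfg["carina_ref"],
                                                 resample_ds=None)
    stack_mv = read_contour_stack(d / "mv_contours.csv", d / "mv_meta.json")
    stack_sb = read_contour_stack(d / "sb_contours.csv", d / "sb_meta.json")
    if stack_mv.branch_label != "MV" or stack_sb.branch_label != "SB":
        raise ValueError(f"{d}: branch labels in metadata do not match files")
    return backbone, stack_mv, stack_sb


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

_LABEL_CODES = {"MV": 0, "SB": 1, "carina-blend": 2}
_CODE_LABELS = {v: k for k, v in _LABEL_CODES.items()}


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write STL (binary), PLY (ascii, with per-face branch labels) or VTK."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "stl":
        mesh.to_trimesh().export(path, file_type="stl")
    elif fmt == "ply":
        _write_ply(mesh, path)
    elif fmt == "vtk":
        _write_vtk_polydata(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    labels = mesh.labels
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write("comment branch label codes: "
                 + ", ".join(f"{v}={k}" for k, v in _LABEL_CODES.items()) + "\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        if labels is not None:
            fh.write("property int branch\n")
        fh.write("end_header\n")
        v32 = mesh.vertices.astype(np.float32)
        for p in v32:
            fh.write(" ".join(repr(float(x)) for x in p) + "\n")
        for i, f in enumerate(mesh.faces):
            row = f"3 {f[0]} {f[1]} {f[2]}"
            if labels is not None:
                row += f" {_LABEL_CODES.get(str(labels[i]), 0)}"
            fh.write(row + "\n")


def _write_vtk_polydata(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbifurcation mesh\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for p in mesh.vertices:
            fh.write(" ".join(_fmt(v) for v in p) + "\n")
        fh.write(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path) -> TriangleMesh:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        tm = trimesh.load(path, file_type="stl", process=True)
        return TriangleMesh(vertices=np.asarray(tm.vertices, float),
                            faces=np.asarray(tm.faces, np.int64))
    if suffix == ".ply":
        return _read_ply(path)
    raise ValueError(f"unsupported mesh format {suffix!r}")


def _read_ply(path: Path) -> TriangleMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0].strip() != "ply" or "ascii" not in lines[1]:
        raise ValueError(f"{path}: not an ascii PLY file")
    n_v = n_f = 0
    has_label = False
    i = 0
    element = None
    for i, ln in enumerate(lines):
        parts = ln.split()
        if parts[:2] == ["element", "vertex"]:
            n_v = int(parts[2])
            element = "vertex"
        elif parts[:2] == ["element", "face"]:
            n_f = int(parts[2])
            element = "face"
        elif parts[:2] == ["property", "int"] and element == "face" \
                and parts[2] == "branch":
            has_label = True
        elif ln.strip() == "end_header":
            break
    body = lines[i + 1:]
    vertices = np.array([r.split() for r in body[:n_v]], dtype=float)
    faces = np.empty((n_f, 3), dtype=np.int64)
    labels = np.empty(n_f, dtype=object) if has_label else None
    for k, row in enumerate(body[n_v:n_v + n_f]):
        parts = row.split()
        faces[k] = [int(parts[1]), int(parts[2]), int(parts[3])]
        if has_label:
            labels[k] = _CODE_LABELS.get(int(parts[4]), "MV")
    return TriangleMesh(vertices=vertices, faces=faces, labels=labels)
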