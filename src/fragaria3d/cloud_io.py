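"""Coloured point cloud and triangle mesh containers plus file I/O.

PLY is the canonical interchange format (binary little-endian with
per-vertex uchar RGB on write; ASCII accepted on read). PCD v0.7 is
supported for PCL interoperability. Coordinates carry no physical units:
scale assignment happens downstream via holder calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh


class CloudIOError(ValueError):
    """Raised for unreadable, colourless, or malformed cloud/mesh files."""


@dataclass
class ColouredCloud:
    """A 3D point cloud with one RGB colour per point.

    Attributes
    ----------
    points : (n, 3) float array
        Coordinates in arbitrary (image-space) units.
    colors : (n, 3) float array
        Per-point RGB, each channel in [0, 1].
    """

    points: np.ndarray
    colors: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        if len(self.points) != len(self.colors):
            raise ValueError(
                f"points ({len(self.points)}) and colors ({len(self.colors)}) "
                "must have equal length"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.colors.size and (self.colors.min() < 0 or self.colors.max() > 1):
            raise ValueError("colour channels must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.points)

    def subset(self, index: np.ndarray) -> "ColouredCloud":
        return ColouredCloud(self.points[index], self.colors[index])

    @staticmethod
    def concatenate(*clouds: "ColouredCloud") -> "ColouredCloud":
        return ColouredCloud(
            np.vstack([c.points for c in clouds]),
            np.vstack([c.colors for c in clouds]),
        )


@dataclass
class TriangleMesh:
    """Triangle mesh sharing the unit system of its source cloud."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be triangles (n, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")


def _normalise_colors(raw: np.ndarray) -> np.ndarray:
    """Map 8-bit or float colours to float RGB in [0, 1]. Idempotent."""
    raw = np.asarray(raw)
    if raw.size == 0:
        raise CloudIOError("no colour attributes in file")
    rgb = raw[:, :3].astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer) or rgb.max() > 1.0:
        rgb = rgb / 255.0
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# PCD v0.7 (no installed library reads it; minimal hand-rolled support)
# ---------------------------------------------------------------------------

def _read_pcd(path: Path) -> ColouredCloud:
    header: dict[str, list[str]] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise CloudIOError(f"truncated PCD header in {path}")
            text = line.decode("ascii", errors="replace").strip()
            if text.startswith("#") or not text:
                continue
            key, *vals = text.split()
            header[key.upper()] = vals
            if key.upper() == "DATA":
                break
        data_kind = header["DATA"][0]
        fields = [f.lower() for f in header["FIELDS"]]
        sizes = [int(s) for s in header["SIZE"]]
        types = header["TYPE"]
        n = int(header["POINTS"][0])
        np_types = {"F": "f", "U": "u", "I": "i"}
        dtype = np.dtype(
            [(f, f"<{np_types[t]}{s}") for f, t, s in zip(fields, types, sizes)]
        )
        if data_kind == "ascii":
            rows = np.loadtxt(fh, dtype=np.float64, ndmin=2)
            rec = np.zeros(n, dtype=dtype)
            for i, f in enumerate(fields):
                col = rows[:, i]
                if types[i] == "U":
                    col = col.astype(f"<u{sizes[i]}")
                rec[f] = col.astype(dtype[f])
        elif data_kind == "binary":
            rec = np.frombuffer(fh.read(n * dtype.itemsize), dtype=dtype, count=n)
        else:
            raise CloudIOError(f"unsupported PCD DATA kind {data_kind!r}")
    pts = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(np.float64)
    if {"r", "g", "b"} <= set(fields):
        cols = np.column_stack([rec["r"], rec["g"], rec["b"]])
    elif "rgb" in fields:
        packed = rec["rgb"]
        if packed.dtype.kind == "f":
            packed = packed.astype("<f4").view("<u4")
        cols = np.column_stack(
            [(packed >> 16) & 0xFF, (packed >> 8) & 0xFF, packed & 0xFF]
        ).astype(np.uint8)
    else:
        raise CloudIOError(f"no colour attributes in PCD file {path}")
    if len(pts) == 0:
        raise CloudIOError(f"zero points in {path}")
    return ColouredCloud(pts, _normalise_colors(cols))


def _write_pcd(cloud: ColouredCloud, path: Path) -> None:
    rgb8 = np.clip(np.round(cloud.colors * 255), 0, 255).astype(np.uint32)
    packed = (rgb8[:, 0] << 16) | (rgb8[:, 1] << 8) | rgb8[:, 2]
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z rgb\nSIZE 4 4 4 4\nTYPE F F F U\n"
        f"COUNT 1 1 1 1\nWIDTH {n}\nHEIGHT 1\n"
        f"VIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    pts = cloud.points.astype(np.float32)
    with open(path, "w") as fh:
        fh.write(header)
        for (x, y, z), c in zip(pts, packed):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {c}\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"ply", "pcd", "obj"}:
        return suffix
    raise CloudIOError(f"cannot infer format from {path.name!r}")


def read_cloud(path, format: str = "auto") -> ColouredCloud:
    """Read a coloured point cloud from PLY or PCD.

    Colours are normalised to [0, 1] regardless of the on-disk encoding.
    Extra vertex properties (alpha, normals, ...) are ignored. A file whose
    vertices carry no RGB attributes is an error: every downstream step is
    colour-driven.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt != "ply":
        raise CloudIOError(f"unsupported cloud format {fmt!r}")
    loaded = trimesh.load(path, process=False)
    if isinstance(loaded, trimesh.Trimesh):
        pts = np.asarray(loaded.vertices, dtype=np.float64)
        colors = getattr(loaded.visual, "vertex_colors", np.empty((0, 4)))
    else:
        pts = np.asarray(loaded.vertices, dtype=np.float64)
        colors = np.asarray(loaded.colors)
    if len(pts) == 0:
        raise CloudIOError(f"zero points in {path}")
    if np.size(colors) == 0:
        raise CloudIOError(f"no colour attributes in {path}")
    return ColouredCloud(pts, _normalise_colors(np.asarray(colors)))


def write_cloud(cloud: ColouredCloud, path, format: str = "auto"):
    """Write a coloured cloud as binary little-endian PLY (default) or PCD."""
    if len(cloud) == 0:
        raise CloudIOError("refusing to write an empty cloud")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pcd":
        _write_pcd(cloud, path)
        return path
    if fmt != "ply":
        raise CloudIOError(f"unsupported cloud format {fmt!r}")
    rgba = np.empty((len(cloud), 4), dtype=np.uint8)
    rgba[:, :3] = np.clip(np.round(cloud.colors * 255), 0, 255).astype(np.uint8)
    rgba[:, 3] = 255
    trimesh.PointCloud(cloud.points, colors=rgba).export(path)
    return path


def write_mesh(mesh: TriangleMesh, path, format: str = "auto"):
    """Write a triangle mesh as PLY or OBJ."""
    if len(mesh.faces) == 0:
        raise CloudIOError("refusing to write an empty mesh")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in {"ply", "obj"}:
        raise CloudIOError(f"unsupported mesh format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)
    return path


def read_mesh(path) -> TriangleMesh:
    """Read a triangle mesh (PLY or OBJ); non-triangle faces are an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(path, process=False, force="mesh")
    faces = np.asarray(tm.faces)
    if faces.size == 0:
        raise CloudIOError(f"no faces in {path}")
    return TriangleMesh(np.asarray(tm.vertices), faces)
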