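"""Divide a watertight model into separately printable parts by plane cuts.

Triangles crossing the plane are split exactly along it (intersection points
shared between neighbouring triangles, so each half stays crack-free), and
the planar openings are capped by the same ear-clipping used for hole
filling.  Because the caps of the two halves triangulate the same planar
polygons, enclosed volume is conserved to floating-point accuracy.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import MeshError, ParameterError
from .mesh import TriangleMesh, save_stl
from .mesh_repair import diagnose, fill_holes

#: vertices closer than this to the plane are snapped onto it (mm)
SNAP_EPS = 1e-9


@dataclass
class CutPlane:
    """An oriented cutting plane: point on plane and unit normal."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ParameterError("plane normal must be non-zero")
        if abs(norm - 1.0) > 1e-9:
            n = n / norm
        self.point = tuple(p)
        self.normal = tuple(n)

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - np.asarray(self.point)) @ np.asarray(self.normal)


def split_by_plane(
    mesh: TriangleMesh, plane: CutPlane, cap: bool = True
) -> tuple[TriangleMesh, TriangleMesh]:
    """Split a watertight, outward-oriented mesh into (positive, negative) halves.

    With ``cap=True`` the cross-section loops of each half are triangulated,
    so both halves are watertight and their volumes sum to the input volume.
    A plane that misses the mesh returns the input on its own side and an
    empty mesh (with a warning).
    """
    diag = diagnose(mesh)
    if not diag.watertight or not diag.outward_oriented:
        raise MeshError("split_by_plane needs a watertight, outward-oriented mesh")

    d = plane.signed_distance(mesh.vertices)
    d = np.where(np.abs(d) <= SNAP_EPS, 0.0, d)

    if np.all(d >= 0):
        warnings.warn("plane misses the mesh; one side is empty", stacklevel=2)
        return mesh.copy(), TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    if np.all(d <= 0):
        warnings.warn("plane misses the mesh; one side is empty", stacklevel=2)
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)), mesh.copy()

    halves = []
    for keep_positive in (True, False):
        verts = [v for v in mesh.vertices]
        cut_vertex: dict[tuple[int, int], int] = {}

        def cut_point(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in cut_vertex:
                da, db = d[a], d[b]
                t = da / (da - db)
                verts.append(mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))
                cut_vertex[key] = len(verts) - 1
            return cut_vertex[key]

        faces = []
        sign = 1.0 if keep_positive else -1.0
        for tri in mesh.triangles:
            ds = sign * d[tri]
            if np.all(ds >= 0):
                if np.any(ds > 0):  # skip triangles lying exactly in the plane
                    faces.append(tuple(tri))
                continue
            if np.all(ds <= 0):
                continue
            # build the clipped polygon in traversal order
            poly: list[int] = []
            for i in range(3):
                j = (i + 1) % 3
                if ds[i] >= 0:
                    poly.append(int(tri[i]))
                if (ds[i] > 0 and ds[j] < 0) or (ds[i] < 0 and ds[j] > 0):
                    poly.append(cut_point(int(tri[i]), int(tri[j])))
            poly = [p for idx, p in enumerate(poly) if p != poly[idx - 1]]
            if len(poly) >= 3:
                for t_i in range(1, len(poly) - 1):
                    a, b, c = poly[0], poly[t_i], poly[t_i + 1]
                    if a != b and b != c and a != c:
                        faces.append((a, b, c))
        if not faces:
            halves.append(TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)))
            continue
        half = TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64)).compact()
        if cap:
            half = fill_holes(half, max_loop_edges=10**6)
        halves.append(half)
    return halves[0], halves[1]


def export_parts(
    parts: list[TriangleMesh],
    labels: list[str],
    directory: str | Path,
    print_parameters: dict | None = None,
) -> Path:
    """Write one STL per part plus a JSON manifest.

    The manifest records label, triangle count, enclosed volume and
    watertightness per part; an optional user print-parameter block is passed
    through untouched.
    """
    if len(parts) != len(labels):
        raise ParameterError("parts and labels must have the same length")
    if len(set(labels)) != len(labels):
        raise ParameterError("part labels must be unique")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for part, label in zip(parts, labels):
        fn = directory / f"{label}.stl"
        save_stl(part, fn)
        entries.append(
            {
                "label": label,
                "file": fn.name,
                "triangle_count": int(part.n_triangles),
                "volume_mm3": float(part.volume()),
                "watertight": bool(part.is_watertight()),
            }
        )
    manifest = {"parts": entries}
    if print_parameters is not None:
        manifest["print_parameters"] = print_parameters
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_manifest(directory: str | Path) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
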