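"""Indexed triangle mesh container and STL input/output.

The mesh is the printable artifact of the pipeline: vertices in mm, faces as
vertex-index triples whose winding defines the normal.  STL serialisation
(binary little-endian with triangle-count header, or ASCII) is delegated to
trimesh; loading welds exactly-coincident vertices since STL stores a
triangle soup.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from . import geometry
from .errors import MeshError


@dataclass
class TriangleMesh:
    """Indexed triangle surface; coordinates in mm."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if len(self.triangles):
            if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
                raise MeshError("triangle index out of range")
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise MeshError("triangle with repeated vertex index")
        if len(self.vertices) and not np.all(np.isfinite(self.vertices)):
            raise MeshError("non-finite vertex coordinates")

    # -- basic measures ----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_empty(self) -> bool:
        return len(self.triangles) == 0

    def normals(self) -> np.ndarray:
        return geometry.triangle_normals(self.vertices, self.triangles)

    def areas(self) -> np.ndarray:
        return geometry.triangle_areas(self.vertices, self.triangles)

    def area(self) -> float:
        return float(self.areas().sum()) if len(self.triangles) else 0.0

    def volume(self) -> float:
        """Signed enclosed volume (positive for outward winding)."""
        return geometry.signed_volume(self.vertices, self.triangles)

    # -- connectivity ------------------------------------------------------
    def edges(self) -> np.ndarray:
        """All directed edges, one row per triangle edge, (3m, 2)."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def edges_sorted_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Undirected unique edges and the incidence count of each."""
        e = np.sort(self.edges(), axis=1)
        if len(e) == 0:
            return e.reshape(0, 2), np.zeros(0, dtype=int)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edge_count(self) -> int:
        _, counts = self.edges_sorted_unique()
        return int(np.sum(counts == 1))

    def nonmanifold_edge_count(self) -> int:
        _, counts = self.edges_sorted_unique()
        return int(np.sum(counts > 2))

    def is_watertight(self) -> bool:
        _, counts = self.edges_sorted_unique()
        return bool(np.all(counts == 2)) if len(counts) else True

    def euler_characteristic(self) -> int:
        """V - E + F over referenced vertices (2 for a topological sphere)."""
        if self.is_empty():
            return 0
        v = len(np.unique(self.triangles))
        e = len(self.edges_sorted_unique()[0])
        f = len(self.triangles)
        return v - e + f

    def face_components(self) -> list[np.ndarray]:
        """Connected components of triangles (adjacency through shared edges)."""
        m = len(self.triangles)
        if m == 0:
            return []
        e = np.sort(self.edges(), axis=1)
        fid = np.tile(np.arange(m), 3)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e_sorted, f_sorted = e[order], fid[order]
        parent = np.arange(m)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        i = 0
        n = len(e_sorted)
        while i < n:
            j = i + 1
            while j < n and (e_sorted[j] == e_sorted[i]).all():
                j += 1
            root = find(f_sorted[i])
            for k in range(i + 1, j):
                parent[find(f_sorted[k])] = root
            i = j
        roots = np.array([find(x) for x in range(m)])
        return [np.flatnonzero(roots == r) for r in np.unique(roots)]

    # -- editing helpers ---------------------------------------------------
    def compact(self) -> "TriangleMesh":
        """Drop unreferenced vertices, remapping triangle indices."""
        if self.is_empty():
            return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        used = np.unique(self.triangles)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[self.triangles])

    def submesh(self, face_idx: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(self.vertices, self.triangles[face_idx]).compact()

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.triangles.copy())

    @staticmethod
    def concatenate(meshes: list["TriangleMesh"]) -> "TriangleMesh":
        if not meshes:
            return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        verts, tris, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            tris.append(m.triangles + off)
            off += len(m.vertices)
        return TriangleMesh(np.concatenate(verts), np.concatenate(tris))

    # -- interop / io ------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.triangles.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))


def save_stl(mesh: TriangleMesh, path: str | Path, ascii_dialect: bool = False) -> Path:
    """Write STL; binary little-endian by default, ASCII on request."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if ascii_dialect:
        path.write_text(tm.export(file_type="stl_ascii"))
    else:
        path.write_bytes(tm.export(file_type="stl"))
    return path


def load_stl(path: str | Path) -> TriangleMesh:
    """Read STL and weld exactly-coincident vertices back into shared indices."""
    tm = trimesh.load(str(path), file_type="stl", process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    keep = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    return TriangleMesh(uniq, faces[keep]).compact()
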