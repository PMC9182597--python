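"""Detect and fix printable-mesh defects.

The checklist mirrors what STL preparation for additive manufacturing has to
verify: inverted normals, gaps (boundary edges / holes), duplicate and
degenerate triangles, free triangles with no bounds, edges without exactly
two incident faces, and enclosed components ("inclusions") invisible from
outside.  ``repair`` runs the stages in a fixed order and reports the defect
census before and after.

Overlapping/intersecting triangle pairs are *counted* (exact duplicates and
coplanar overlaps); general intersection surgery is out of scope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import MeshError
from .geometry import ear_clip, ray_parity_inside, triangle_areas
from .mesh import TriangleMesh


@dataclass
class MeshDiagnostics:
    """Defect census of one mesh."""

    boundary_edge_count: int
    non_manifold_edge_count: int
    duplicate_triangle_count: int
    degenerate_triangle_count: int
    inconsistent_orientation_pair_count: int
    connected_component_count: int
    enclosed_component_count: int
    free_triangle_count: int
    watertight: bool
    outward_oriented: bool
    empty: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def diagnose(
    mesh: TriangleMesh,
    area_eps: float = 1e-9,
    min_component_triangles: int = 4,
) -> MeshDiagnostics:
    """Compute every checklist field; deterministic.

    An empty mesh is reported as watertight by convention and flagged empty.
    """
    if mesh.is_empty():
        return MeshDiagnostics(0, 0, 0, 0, 0, 0, 0, 0, True, True, empty=True)

    edges, counts = mesh.edges_sorted_unique()
    boundary = int(np.sum(counts == 1))
    nonmanifold = int(np.sum(counts > 2))

    tri_sorted = np.sort(mesh.triangles, axis=1)
    uniq_tris = np.unique(tri_sorted, axis=0)
    duplicates = len(tri_sorted) - len(uniq_tris)

    degenerate = int(np.sum(triangle_areas(mesh.vertices, mesh.triangles) < area_eps))

    inconsistent = _inconsistent_pairs(mesh)

    comps = mesh.face_components()
    free = sum(len(c) for c in comps if len(c) < min_component_triangles)
    enclosed = _enclosed_components(mesh, comps)

    watertight = boundary == 0 and nonmanifold == 0
    return MeshDiagnostics(
        boundary_edge_count=boundary,
        non_manifold_edge_count=nonmanifold,
        duplicate_triangle_count=duplicates,
        degenerate_triangle_count=degenerate,
        inconsistent_orientation_pair_count=inconsistent,
        connected_component_count=len(comps),
        enclosed_component_count=enclosed,
        free_triangle_count=free,
        watertight=watertight,
        outward_oriented=mesh.volume() > 0,
    )


def _inconsistent_pairs(mesh: TriangleMesh) -> int:
    """Adjacent-face pairs traversing their shared edge in the same direction."""
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    key = np.sort(directed, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    d_sorted = directed[order]
    k_sorted = key[order]
    inconsistent = 0
    i, n = 0, len(k_sorted)
    while i < n:
        j = i + 1
        while j < n and (k_sorted[j] == k_sorted[i]).all():
            j += 1
        if j - i == 2:
            # consistent orientation means opposite traversal directions
            if (d_sorted[i] == d_sorted[i + 1]).all():
                inconsistent += 1
        i = j
    return inconsistent


def _component_closed(mesh: TriangleMesh, comp: np.ndarray) -> bool:
    sub = TriangleMesh(mesh.vertices, mesh.triangles[comp])
    _, counts = sub.edges_sorted_unique()
    return bool(np.all(counts == 2))


def _enclosed_components(mesh: TriangleMesh, comps: list[np.ndarray]) -> int:
    if len(comps) < 2:
        return 0
    closed = [_component_closed(mesh, c) for c in comps]
    enclosed = 0
    for i, ci in enumerate(comps):
        probe = mesh.vertices[mesh.triangles[ci[0], 0]][None, :]
        for j, cj in enumerate(comps):
            if i == j or not closed[j]:
                continue
            if ray_parity_inside(probe, mesh.vertices, mesh.triangles[cj])[0]:
                enclosed += 1
                break
    return enclosed


def fix_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Make winding consistent per component and flip closed components outward.

    Orientation is propagated by flood fill over edge-adjacent triangles;
    afterwards each closed component with negative signed volume is flipped
    so all normals point out of the enclosed solid.  Vertex coordinates and
    triangle count are never changed.
    """
    if mesh.is_empty():
        return mesh.copy()
    if mesh.nonmanifold_edge_count() > 0:
        raise MeshError(
            "non-manifold edges present; run debris removal before fix_normals"
        )
    tris = mesh.triangles.copy()
    m = len(tris)

    # adjacency: edge key -> incident faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi in range(m):
        t = tris[fi]
        for x, y in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_faces.setdefault((min(x, y), max(x, y)), []).append(fi)

    visited = np.zeros(m, dtype=bool)
    comp_of = np.full(m, -1, dtype=int)
    n_comp = 0
    for start in range(m):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp_of[start] = n_comp
        while stack:
            f = stack.pop()
            t = tris[f]
            for x, y in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                for g in edge_faces[(min(x, y), max(x, y))]:
                    if visited[g]:
                        continue
                    tg = tris[g]
                    # does g traverse the shared edge in the same direction?
                    same = any(
                        (tg[i], tg[(i + 1) % 3]) == (x, y) for i in range(3)
                    )
                    if same:
                        tris[g] = tg[::-1]
                    visited[g] = True
                    comp_of[g] = n_comp
                    stack.append(g)
        n_comp += 1

    for c in range(n_comp):
        idx = np.flatnonzero(comp_of == c)
        sub = TriangleMesh(mesh.vertices, tris[idx])
        if sub.boundary_edge_count() == 0 and sub.volume() < 0:
            tris[idx] = tris[idx][:, ::-1]
    return TriangleMesh(mesh.vertices.copy(), tris)


def _boundary_loops(mesh: TriangleMesh) -> list[list[int]]:
    """Boundary loops as vertex sequences, following face traversal direction."""
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    key = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inverse] == 1
    bdir = directed[on_boundary]

    nxt: dict[int, int] = {}
    non_simple = set()
    for a, b in bdir:
        if int(a) in nxt:
            non_simple.add(int(a))
        nxt[int(a)] = int(b)
    loops = []
    seen: set[int] = set()
    for start in sorted(nxt):
        if start in seen or start in non_simple:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt.get(start)
        ok = True
        while cur is not None and cur != start:
            if cur in seen or cur in non_simple:
                ok = False
                break
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if ok and cur == start and len(loop) >= 3:
            loops.append(loop)
        elif not ok or cur is None:
            warnings.warn("non-simple boundary loop skipped", stacklevel=3)
    return loops


def fill_holes(mesh: TriangleMesh, max_loop_edges: int = 100) -> TriangleMesh:
    """Triangulate boundary loops with up to ``max_loop_edges`` edges.

    Each hole is ear-clipped (minimal-area ear first) with winding opposite
    to the surrounding faces' traversal, so the patch is orientation
    consistent with its surroundings.  Larger or non-simple loops are left
    with a warning.
    """
    if mesh.is_empty():
        return mesh.copy()
    new_faces = []
    for loop in _boundary_loops(mesh):
        if len(loop) > max_loop_edges:
            warnings.warn(
                f"boundary loop with {len(loop)} edges exceeds max_loop_edges; left open",
                stacklevel=2,
            )
            continue
        ring = loop[::-1]  # patch traverses opposite to the existing faces
        pts = mesh.vertices[ring]
        for a, b, c in ear_clip(pts):
            new_faces.append((ring[a], ring[b], ring[c]))
    if not new_faces:
        return mesh.copy()
    tris = np.concatenate([mesh.triangles, np.asarray(new_faces, dtype=np.int64)])
    return TriangleMesh(mesh.vertices.copy(), tris)


def _dedupe(tris: np.ndarray) -> np.ndarray:
    if len(tris) == 0:
        return tris
    _, first_idx = np.unique(np.sort(tris, axis=1), axis=0, return_index=True)
    return tris[np.sort(first_idx)]


def remove_debris(
    mesh: TriangleMesh,
    min_component_triangles: int = 4,
    area_eps: float = 1e-6,
    weld_tol: float = 1e-3,
) -> TriangleMesh:
    """Drop duplicate triangles, weld away slivers, remove tiny components.

    Degenerate triangles (area < ``area_eps`` mm²) are eliminated by
    collapsing their shortest edge when it is below ``weld_tol`` mm — this
    removes the sliver without puncturing an otherwise closed surface, which
    matters for marching-cubes output whose crossings can sit arbitrarily
    close to a grid corner.  A degenerate triangle whose edges are all long
    (three nearly-collinear but distant vertices) is kept, since deleting it
    would open the mesh.
    """
    if mesh.is_empty():
        return mesh.copy()
    verts = mesh.vertices.copy()
    tris = _dedupe(mesh.triangles.copy())

    for _ in range(10):
        if len(tris) == 0:
            break
        areas = triangle_areas(verts, tris)
        sliver_ids = np.flatnonzero(areas < area_eps)
        if len(sliver_ids) == 0:
            break
        parent = np.arange(len(verts))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        welded = False
        for ti in sliver_ids:
            corners = [find(int(v)) for v in tris[ti]]
            pairs = [(corners[0], corners[1]), (corners[1], corners[2]), (corners[2], corners[0])]
            lens = [np.linalg.norm(verts[x] - verts[y]) for x, y in pairs]
            i = int(np.argmin(lens))
            x, y = pairs[i]
            if x != y and lens[i] < weld_tol:
                mid = (verts[x] + verts[y]) / 2.0
                root, child = (x, y) if x < y else (y, x)
                parent[child] = root
                verts[root] = mid
                welded = True
        if not welded:
            break
        remap = np.array([find(v) for v in range(len(verts))])
        tris = remap[tris]
        ok = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
        tris = _dedupe(tris[ok])

    work = TriangleMesh(verts, tris)
    if work.is_empty():
        return work.compact()
    comps = work.face_components()
    good = np.concatenate(
        [c for c in comps if len(c) >= min_component_triangles]
    ) if any(len(c) >= min_component_triangles for c in comps) else np.zeros(0, dtype=int)
    return TriangleMesh(work.vertices, work.triangles[good.astype(int)]).compact()


def remove_inclusions(mesh: TriangleMesh) -> TriangleMesh:
    """Delete closed components fully enclosed by another closed component."""
    if mesh.is_empty():
        return mesh.copy()
    comps = mesh.face_components()
    for c in comps:
        if not _component_closed(mesh, c):
            raise MeshError("open component; run fill_holes before remove_inclusions")
    if len(comps) < 2:
        return mesh.copy()
    keep_faces = []
    for i, ci in enumerate(comps):
        probe = mesh.vertices[mesh.triangles[ci[0], 0]][None, :]
        inside_any = False
        for j, cj in enumerate(comps):
            if i == j:
                continue
            if ray_parity_inside(probe, mesh.vertices, mesh.triangles[cj])[0]:
                inside_any = True
                break
        if not inside_any:
            keep_faces.append(ci)
    if not keep_faces:
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    return TriangleMesh(
        mesh.vertices, mesh.triangles[np.concatenate(keep_faces)]
    ).compact()


def repair(
    mesh: TriangleMesh,
    min_component_triangles: int = 4,
    area_eps: float = 1e-6,
    max_loop_edges: int = 100,
) -> tuple[TriangleMesh, MeshDiagnostics, MeshDiagnostics]:
    """Full repair chain; returns (mesh, diagnostics before, diagnostics after).

    Order: debris removal -> hole filling -> normal unification ->
    inclusion removal.  Idempotent: repairing an already-clean mesh leaves
    geometry and diagnostics unchanged.
    """
    before = diagnose(mesh, min_component_triangles=min_component_triangles)
    if mesh.is_empty():
        warnings.warn("repairing an empty mesh", stacklevel=2)
        return mesh.copy(), before, before
    out = remove_debris(mesh, min_component_triangles, area_eps)
    if not out.is_empty():
        out = fill_holes(out, max_loop_edges)
        if out.nonmanifold_edge_count() == 0:
            out = fix_normals(out)
            if out.boundary_edge_count() > 0:
                # inverted windings at a hole rim prevent loop walking until
                # orientation is unified; fill again now that it is
                out = fill_holes(out, max_loop_edges)
                out = fix_normals(out)
        if out.boundary_edge_count() == 0 and out.nonmanifold_edge_count() == 0:
            out = remove_inclusions(out)
        else:
            warnings.warn("mesh still open after fill_holes; inclusions kept", stacklevel=2)
    after = diagnose(out, min_component_triangles=min_component_triangles)
    return out, before, after
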