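"""Low-level geometric primitives shared by the meshing, repair, splitting
and metrology stages.

Everything here operates on raw numpy arrays (vertices ``(n, 3)`` float in mm,
faces ``(m, 3)`` int) so that the higher-level modules can share one tested
implementation of triangle measures, point-to-triangle projection, ray-parity
containment and polygon ear clipping.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "triangle_normals",
    "triangle_areas",
    "signed_volume",
    "newell_normal",
    "point_triangle_closest",
    "closest_on_mesh",
    "ray_parity_inside",
    "ear_clip",
]


def triangle_normals(vertices: np.ndarray, faces: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-triangle normals from winding order (right-hand rule)."""
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    if normalize:
        norm = np.linalg.norm(n, axis=1)
        norm = np.where(norm == 0.0, 1.0, norm)
        n = n / norm[:, None]
    return n


def triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume by the divergence theorem.

    Positive when the winding makes normals point outward.  Only meaningful
    for closed surfaces, but computable for any triangle soup.
    """
    if len(faces) == 0:
        return 0.0
    a, b, c = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def newell_normal(poly: np.ndarray) -> np.ndarray:
    """Robust plane normal of a closed 3-D polygon (Newell's method)."""
    p = np.asarray(poly, dtype=float)
    q = np.roll(p, -1, axis=0)
    n = np.array(
        [
            np.sum((p[:, 1] - q[:, 1]) * (p[:, 2] + q[:, 2])),
            np.sum((p[:, 2] - q[:, 2]) * (p[:, 0] + q[:, 0])),
            np.sum((p[:, 0] - q[:, 0]) * (p[:, 1] + q[:, 1])),
        ]
    )
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else np.array([0.0, 0.0, 1.0])


def point_triangle_closest(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a, b, c) to p, all arrays ``(n, 3)``.

    Vectorised version of the classic Voronoi-region walk (Ericson,
    *Real-Time Collision Detection*, §5.1.5).
    """
    p = np.atleast_2d(p).astype(float)
    a = np.broadcast_to(a, p.shape).astype(float)
    b = np.broadcast_to(b, p.shape).astype(float)
    c = np.broadcast_to(c, p.shape).astype(float)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, values):
        m = mask & ~done
        if np.any(m):
            out[m] = values[m] if values.shape == p.shape else values
            done[m] = True

    # vertex regions
    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)

    # edge AB
    denom_ab = np.where(d1 - d3 == 0, 1.0, d1 - d3)
    v_ab = d1 / denom_ab
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.clip(v_ab, 0, 1)[:, None] * ab)

    # edge AC
    denom_ac = np.where(d2 - d6 == 0, 1.0, d2 - d6)
    w_ac = d2 / denom_ac
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.clip(w_ac, 0, 1)[:, None] * ac)

    # edge BC
    denom_bc = np.where((d4 - d3) + (d5 - d6) == 0, 1.0, (d4 - d3) + (d5 - d6))
    w_bc = (d4 - d3) / denom_bc
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + np.clip(w_bc, 0, 1)[:, None] * (c - b))

    # interior
    if not np.all(done):
        s = va + vb + vc
        s = np.where(s == 0, 1.0, s)
        v = vb / s
        w = vc / s
        interior = a + v[:, None] * ab + w[:, None] * ac
        out[~done] = interior[~done]
    return out


def closest_on_mesh(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    k: int = 48,
    tree: cKDTree | None = None,
):
    """Nearest point on a triangle mesh for each query point.

    Candidate triangles are pre-selected by a KD-tree over triangle
    centroids (``k`` nearest), then resolved exactly.  Adequate for meshes
    with roughly uniform triangle size, which is what marching cubes emits.

    Returns ``(distances, closest_points, face_indices)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(faces)
    if m == 0:
        raise ValueError("mesh has no triangles")
    tri = vertices[faces]  # (m, 3, 3)
    if tree is None:
        tree = cKDTree(tri.mean(axis=1))
    kk = min(k, m)
    _, cand = tree.query(points, k=kk)
    cand = np.atleast_2d(cand)
    if kk == 1:
        cand = cand.reshape(-1, 1)

    n = len(points)
    rep = np.repeat(points, kk, axis=0)
    flat = cand.ravel()
    cp = point_triangle_closest(rep, tri[flat, 0], tri[flat, 1], tri[flat, 2])
    d = np.linalg.norm(cp - rep, axis=1).reshape(n, kk)
    best = np.argmin(d, axis=1)
    idx = np.arange(n)
    closest = cp.reshape(n, kk, 3)[idx, best]
    return d[idx, best], closest, cand[idx, best]


_RAY_DIRECTIONS = np.array(
    [
        [0.5381290, 0.3127389, 0.7827417],
        [0.8133061, -0.2470913, 0.5268421],
        [-0.3312781, 0.7423150, 0.5823250],
        [0.1192301, -0.5523901, -0.8250214],
        [-0.7091295, -0.4123789, 0.5716621],
        [0.2701347, 0.8912237, -0.3642118],
        [-0.5912001, 0.2213307, -0.7755312],
        [0.9210377, 0.3312311, 0.2051128],
    ]
)
_RAY_DIRECTIONS /= np.linalg.norm(_RAY_DIRECTIONS, axis=1)[:, None]


def ray_parity_inside(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    chunk: int = 256,
) -> np.ndarray:
    """Even–odd containment test for each point against a closed surface.

    Casts a ray along a fixed direction and counts triangle crossings
    (Möller–Trumbore).  Hits too close to a triangle edge/plane are resolved
    by deterministically retrying with the next direction from a fixed list,
    so results are reproducible.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(faces) == 0:
        return np.zeros(len(points), dtype=bool)
    tri = vertices[faces]
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0

    inside = np.zeros(len(points), dtype=bool)
    for start in range(0, len(points), chunk):
        pts = points[start : start + chunk]
        res = np.zeros(len(pts), dtype=bool)
        pending = np.ones(len(pts), dtype=bool)
        last_parity = np.zeros(len(pts), dtype=bool)
        for d in _RAY_DIRECTIONS:
            if not np.any(pending):
                break
            p = pts[pending]
            h = np.cross(d, e2)  # (m, 3)
            det = np.einsum("ij,ij->i", e1, h)  # (m,)
            ok = np.abs(det) > 1e-12
            inv = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
            s = p[:, None, :] - v0[None, :, :]  # (n, m, 3)
            u = np.einsum("nmj,mj->nm", s, h) * inv[None, :]
            q = np.cross(s, e1[None, :, :])
            v = np.einsum("nmj,j->nm", q, d) * inv[None, :]
            t = np.einsum("nmj,mj->nm", q, e2) * inv[None, :]
            eps = 1e-9
            hit = ok[None, :] & (t > eps) & (u > eps) & (v > eps) & (u + v < 1 - eps)
            # a crossing too close to an edge/vertex/plane of any triangle
            # makes the parity unreliable -> retry with the next ray
            grazing = (
                ok[None, :]
                & (
                    (np.abs(u) <= eps)
                    | (np.abs(v) <= eps)
                    | (np.abs(1 - u - v) <= eps)
                    | (np.abs(t) <= eps)
                )
                & (u > -eps)
                & (v > -eps)
                & (u + v < 1 + eps)
                & (t > -eps)
            )
            ambiguous = grazing.any(axis=1)
            parity = (hit.sum(axis=1) % 2) == 1
            idx = np.flatnonzero(pending)
            last_parity[idx] = parity
            resolved = ~ambiguous
            res[idx[resolved]] = parity[resolved]
            pending[idx[resolved]] = False
        # points ambiguous for every ray direction: accept last parity
        res[pending] = last_parity[pending]
        inside[start : start + chunk] = res
    return inside


def _project_2d(poly: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Project 3-D polygon points onto a 2-D basis of the plane ⟂ normal."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.column_stack([poly @ u, poly @ v])


def _point_in_tri_2d(p, a, b, c, eps=1e-12):
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    has_neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    has_pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (has_neg and has_pos)


def ear_clip(poly: np.ndarray, normal: np.ndarray | None = None) -> list[tuple[int, int, int]]:
    """Triangulate a simple closed polygon given as an ordered vertex ring.

    The winding of the emitted triangles follows the input order.  Ears are
    clipped smallest-area first among valid candidates (convex corner, no
    other remaining vertex inside), falling back to the least-degenerate
    corner when numerical noise leaves no strictly valid ear.
    """
    poly = np.asarray(poly, dtype=float)
    m = len(poly)
    if m < 3:
        return []
    if m == 3:
        return [(0, 1, 2)]
    if normal is None:
        normal = newell_normal(poly)
    pts = _project_2d(poly, normal)
    # Ensure CCW in the projected frame so "convex" has one sign.
    area2 = np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    flipped = area2 < 0
    if flipped:
        pts = pts * np.array([1.0, -1.0])

    remaining = list(range(m))
    tris: list[tuple[int, int, int]] = []
    while len(remaining) > 3:
        best = None
        best_area = np.inf
        L = len(remaining)
        for pos in range(L):
            i0 = remaining[(pos - 1) % L]
            i1 = remaining[pos]
            i2 = remaining[(pos + 1) % L]
            a, b, c = pts[i0], pts[i1], pts[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate corner
            blocked = False
            for j in remaining:
                if j in (i0, i1, i2):
                    continue
                if _point_in_tri_2d(pts[j], a, b, c):
                    blocked = True
                    break
            if blocked:
                continue
            if 0.5 * cross < best_area:
                best_area = 0.5 * cross
                best = pos
        if best is None:
            # numerical fallback: clip the corner with the largest convexity
            crosses = []
            for pos in range(L):
                a = pts[remaining[(pos - 1) % L]]
                b = pts[remaining[pos]]
                c = pts[remaining[(pos + 1) % L]]
                crosses.append((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
            best = int(np.argmax(crosses))
        L = len(remaining)
        i0 = remaining[(best - 1) % L]
        i1 = remaining[best]
        i2 = remaining[(best + 1) % L]
        tris.append((i0, i1, i2))
        remaining.pop(best)
    tris.append(tuple(remaining))
    return tris
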