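"""Marching-cubes combinatorics, extraction fidelity, subdivision, decimation."""
import numpy as np
import pytest

import osteoprint as op
from osteoprint import surface
from osteoprint.errors import ParameterError


# --- independent orbit-enumeration oracle ----------------------------------

def _rotation_group_from_generators():
    """Closure of two generator rotations; must be the 24 proper rotations."""
    rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])  # 90 deg about z
    rx = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]])  # 90 deg about x
    group = {np.eye(3, dtype=int).tobytes()}
    frontier = [np.eye(3, dtype=int)]
    while frontier:
        nxt = []
        for M in frontier:
            for g in (rz, rx):
                P = g @ M
                key = P.tobytes()
                if key not in group:
                    group.add(key)
                    nxt.append(P)
        frontier = nxt
    return [np.frombuffer(k, dtype=int).reshape(3, 3) for k in group]


def _oracle_classes():
    rots = _rotation_group_from_generators()
    assert len(rots) == 24
    corners = np.array([[(c >> a) & 1 for a in range(3)] for c in range(8)])
    perms = []
    for M in rots:
        rotated = (corners - 0.5) @ M.T + 0.5
        perms.append(
            [int(r[0] + 2 * r[1] + 4 * r[2]) for r in np.round(rotated).astype(int)]
        )

    def canon(cfg):
        best = 255
        for perm in perms:
            for base in (cfg, cfg ^ 0xFF):
                img = 0
                for c in range(8):
                    if base >> c & 1:
                        img |= 1 << perm[c]
                best = min(best, img)
        return best

    return {canon(cfg) for cfg in range(256)}, canon


class TestCaseEnumeration:
    def test_total_configurations(self):
        _, class_of = op.enumerate_mc_classes()
        assert len(class_of) == 256

    def test_fifteen_canonical_classes(self):
        n, _ = op.enumerate_mc_classes()
        assert n == 15

    def test_all_inside_and_all_outside_share_a_class(self):
        _, class_of = op.enumerate_mc_classes()
        assert class_of[0] == class_of[255]

    def test_partition_matches_independent_oracle(self):
        n, class_of = op.enumerate_mc_classes()
        canon_set, canon = _oracle_classes()
        assert len(canon_set) == n
        # identical partition: same-class iff same canonical form
        canons = [canon(cfg) for cfg in range(256)]
        for a in range(256):
            for b in range(a + 1, 256):
                assert (class_of[a] == class_of[b]) == (canons[a] == canons[b])


class TestCaseTable:
    def test_single_inside_corner_yields_one_triangle(self):
        table = op.mc_table()
        for corner in range(8):
            assert len(table.triangles[1 << corner]) == 1

    def test_empty_configurations(self):
        table = op.mc_table()
        assert table.triangles[0] == []
        assert table.triangles[255] == []

    def test_crossed_edges_are_exactly_sign_change_edges(self):
        table = op.mc_table()
        for cfg in range(256):
            used = {e for tri in table.triangles[cfg] for e in tri}
            expected = {
                i
                for i, (a, b) in enumerate(surface.EDGE_CORNERS)
                if ((cfg >> a) & 1) != ((cfg >> b) & 1)
            }
            assert used == expected


class TestExtraction:
    def test_ball_is_watertight_topological_sphere(self):
        mesh = op.extract_isosurface(op.sphere_distance_volume(10.0, 0.5), 0.0)
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2

    def test_ball_area_and_volume_match_analytic(self):
        mesh = op.extract_isosurface(op.sphere_distance_volume(10.0, 0.5), 0.0)
        assert abs(mesh.area() - 4 * np.pi * 100) / (4 * np.pi * 100) < 0.03
        vol_true = 4 / 3 * np.pi * 1000
        assert abs(mesh.volume() - vol_true) / vol_true < 0.015

    def test_iso_outside_range_returns_empty_with_warning(self):
        vol = op.HUVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            mesh = op.extract_isosurface(vol, 10.0)
        assert mesh.is_empty()

    def test_interior_random_masks_are_crack_free(self, rng):
        for _ in range(100):
            arr = np.zeros((6, 6, 6), dtype=np.uint8)
            arr[1:5, 1:5, 1:5] = rng.random((4, 4, 4)) < 0.5
            if arr.sum() == 0:
                continue
            mask = op.BinaryMask(arr, (1, 1, 1))
            mesh = op.extract_isosurface(mask, 0.5)
            assert mesh.boundary_edge_count() == 0

    def test_noisy_mask_output_is_manifold(self, rng):
        # ambiguous cells abound in noisy masks; the face-safe fan-root rule
        # must keep every edge on exactly two triangles
        for _ in range(20):
            arr = np.zeros((10, 10, 10), dtype=np.uint8)
            arr[1:9, 1:9, 1:9] = rng.random((8, 8, 8)) < 0.5
            if arr.sum() == 0:
                continue
            mesh = op.extract_isosurface(op.BinaryMask(arr, (1, 1, 1)), 0.5)
            assert mesh.boundary_edge_count() == 0
            assert mesh.nonmanifold_edge_count() == 0

    def test_agrees_with_reference_marching_cubes_on_smooth_field(self, rng):
        from skimage import measure
        from scipy.ndimage import gaussian_filter

        # smooth random field; ambiguous cells are resolved differently by the
        # two implementations, so agreement is approximate and improves with
        # field smoothness
        field = gaussian_filter(rng.normal(size=(24, 24, 24)), 3.0)
        iso = float(np.median(field))
        ours = op.extract_isosurface(op.HUVolume(field * 100, (1, 1, 1)), iso * 100)
        verts, faces, _, _ = measure.marching_cubes(field, iso)
        ref = op.TriangleMesh(verts, faces)
        assert abs(ours.area() - ref.area()) / ref.area() < 0.02
        assert abs(abs(ours.volume()) - abs(ref.volume())) / abs(ref.volume()) < 0.02


class TestSubdivide:
    def test_short_edges_untouched(self, unit_cube_mesh):
        out = op.subdivide(unit_cube_mesh, max_edge=2.0)
        assert out.n_triangles == unit_cube_mesh.n_triangles

    def test_single_triangle_midpoint_split(self):
        tri = op.TriangleMesh(
            np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], dtype=float), np.array([[0, 1, 2]])
        )
        out = op.subdivide(tri, max_edge=np.sqrt(2.0))
        assert out.n_triangles == 4
        assert out.area() == pytest.approx(tri.area())

    def test_watertight_preserved_and_edges_bounded(self, ball_mesh):
        out = op.subdivide(ball_mesh, max_edge=0.7)
        assert out.boundary_edge_count() == 0
        e = out.vertices[out.edges()]
        lengths = np.linalg.norm(e[:, 0] - e[:, 1], axis=1)
        assert lengths.max() <= 0.7 + 1e-12
        assert out.volume() == pytest.approx(ball_mesh.volume(), rel=1e-9)

    def test_nonpositive_max_edge_rejected(self, unit_cube_mesh):
        with pytest.raises(ParameterError):
            op.subdivide(unit_cube_mesh, 0.0)


def _plane_grid_mesh(n=24, pitch=1.0):
    """Dense triangulated planar grid (2 n^2 triangles)."""
    xs, ys = np.meshgrid(np.arange(n + 1) * pitch, np.arange(n + 1) * pitch, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros((n + 1) ** 2)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces += [(a, b, d), (a, d, c)]
    return op.TriangleMesh(verts, np.array(faces))


class TestDecimate:
    def test_vanishing_tolerance_keeps_curved_mesh(self, ball_mesh):
        out = op.decimate(ball_mesh, chord_tol=1e-12, angle_tol=1e-6)
        assert out.n_triangles == ball_mesh.n_triangles

    def test_planar_grid_collapses_with_tiny_error(self):
        grid = _plane_grid_mesh()
        out = op.decimate(grid, chord_tol=0.01, angle_tol=25.0)
        assert out.n_triangles <= 0.1 * grid.n_triangles
        # every vertex stays on the plane z=0
        assert np.abs(out.vertices[:, 2]).max() <= 0.01

    def test_sphere_chord_audit_holds(self, ball_mesh):
        out = op.decimate(ball_mesh, chord_tol=0.05, angle_tol=30.0)
        assert out.n_triangles < ball_mesh.n_triangles
        from osteoprint.geometry import closest_on_mesh

        d, _, _ = closest_on_mesh(ball_mesh.vertices, out.vertices, out.triangles)
        assert d.max() <= 0.05 + 1e-9

    def test_watertight_stays_watertight(self, ball_mesh):
        out = op.decimate(ball_mesh, chord_tol=0.05, angle_tol=30.0)
        assert out.is_watertight()

    def test_bad_tolerances_rejected(self, ball_mesh):
        with pytest.raises(ParameterError):
            op.decimate(ball_mesh, chord_tol=0.0)
        with pytest.raises(ParameterError):
            op.decimate(ball_mesh, chord_tol=0.1, angle_tol=0.0)


class TestConvergence:
    def test_ball_errors_decrease_monotonically_with_resolution(self):
        area_true = 4 * np.pi * 100
        vol_true = 4 / 3 * np.pi * 1000
        area_err, vol_err = [], []
        for spacing in (1.0, 0.5, 0.25):
            mesh = op.extract_isosurface(op.sphere_distance_volume(10.0, spacing), 0.0)
            area_err.append(abs(mesh.area() - area_true) / area_true)
            vol_err.append(abs(mesh.volume() - vol_true) / vol_true)
        assert area_err[0] > area_err[1] > area_err[2]
        assert vol_err[0] > vol_err[1] > vol_err[2]
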