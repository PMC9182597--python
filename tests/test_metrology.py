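"""Best-fit registration, deviation statistics and areal surface texture."""
import numpy as np
import pytest

import osteoprint as op
from osteoprint.errors import MeshError, ParameterError, RegistrationError
from osteoprint.geometry import closest_on_mesh
from osteoprint.metrology import ALPHA, RigidTransform


def _random_transform(rng, max_deg=20.0, max_trans=10.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
    return RigidTransform(R, rng.uniform(-max_trans, max_trans, 3))


class TestBestFit:
    def test_points_on_mesh_stay_fixed(self, box_mesh):
        pts = box_mesh.vertices[::5]
        t = op.best_fit(pts, box_mesh, tol=1e-7)
        d, _, _ = closest_on_mesh(t.apply(pts), box_mesh.vertices, box_mesh.triangles)
        assert np.sqrt((d**2).mean()) < 1e-6
        assert np.allclose(t.rotation, np.eye(3), atol=1e-6)

    def test_recovers_known_rigid_displacement(self, box_mesh, rng):
        pts = box_mesh.vertices[rng.choice(len(box_mesh.vertices), 300, replace=False)]
        truth = _random_transform(rng)
        moved = truth.apply(pts)
        rec = op.best_fit(moved, box_mesh, tol=1e-7, max_iter=300)
        d, _, _ = closest_on_mesh(rec.apply(moved), box_mesh.vertices, box_mesh.triangles)
        assert np.sqrt((d**2).mean()) < 1e-3
        # the recovered transform inverts the displacement
        assert np.allclose(rec.rotation @ truth.rotation, np.eye(3), atol=1e-4)

    def test_two_points_rejected(self, box_mesh):
        with pytest.raises(RegistrationError):
            op.best_fit(np.array([[0, 0, 0], [1, 0, 0.0]]), box_mesh)

    def test_collinear_points_rejected(self, box_mesh):
        pts = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(RegistrationError):
            op.best_fit(pts, box_mesh)

    def test_nonconvergence_warns(self, box_mesh, rng):
        pts = box_mesh.vertices[::7] + rng.normal(0, 2.0, (len(box_mesh.vertices[::7]), 3))
        with pytest.warns(UserWarning, match="converge"):
            op.best_fit(pts, box_mesh, tol=1e-12, max_iter=2)


class TestDeviationReport:
    def test_points_on_surface_have_zero_moments(self, ball_mesh):
        report = op.deviation_report(ball_mesh.vertices[::4], ball_mesh)
        assert abs(report.mean_deviation) < 1e-9
        assert report.standard_deviation < 1e-9

    def test_radial_offset_gives_positive_mean(self, ball_mesh):
        center = ball_mesh.vertices.mean(axis=0)
        v = ball_mesh.vertices[::4]
        r = v - center
        pts = v + 0.2 * r / np.linalg.norm(r, axis=1)[:, None]
        report = op.deviation_report(pts, ball_mesh)
        assert report.mean_deviation == pytest.approx(0.2, abs=0.02)
        assert report.standard_deviation < 0.02

    def test_symmetric_offsets_give_zero_mean_sigma_d(self, ball_mesh):
        center = ball_mesh.vertices.mean(axis=0)
        v = ball_mesh.vertices[::4]
        u = (v - center) / np.linalg.norm(v - center, axis=1)[:, None]
        d = 0.3
        signs = np.where(np.arange(len(v)) % 2 == 0, 1.0, -1.0)
        pts = v + signs[:, None] * d * u
        report = op.deviation_report(pts, ball_mesh)
        assert abs(report.mean_deviation) < 0.02
        assert report.standard_deviation == pytest.approx(d, rel=0.1)

    def test_open_mesh_requires_unsigned(self, unit_cube_mesh):
        holed = op.TriangleMesh(unit_cube_mesh.vertices, unit_cube_mesh.triangles[:-1])
        with pytest.raises(MeshError):
            op.deviation_report(np.zeros((4, 3)), holed)
        with pytest.warns(UserWarning, match="unsigned"):
            report = op.deviation_report(unit_cube_mesh.vertices[:4], holed, signed=False)
        assert np.all(report.distances >= 0)

    def test_sigma_estimates_point_noise_on_plane(self, rng):
        # flat slab; points above the top face with Gaussian height noise
        slab = op.extract_isosurface(op.box_distance_volume((20.0, 20.0, 2.0), 1.0), 0.0)
        s = 0.08
        n = 10_000
        center = slab.vertices.mean(axis=0)
        xy = center[:2] + rng.uniform(-15.0, 15.0, size=(n, 2))
        top = slab.vertices[:, 2].max()
        pts = np.column_stack([xy[:, 0], xy[:, 1], np.full(n, top) + rng.normal(0, s, n)])
        report = op.deviation_report(pts, slab)
        assert report.standard_deviation == pytest.approx(s, rel=0.1)


class TestRemoveForm:
    def _hm(self, values, spacing=0.02):
        return op.HeightMap(np.asarray(values, dtype=float), spacing)

    def test_exact_quadratic_removed(self):
        x, y = np.meshgrid(np.arange(40) * 0.02, np.arange(40) * 0.02, indexing="ij")
        hm = self._hm(3 + 2 * x - y + 0.5 * x * x - x * y + 0.2 * y * y)
        out = op.remove_form(hm, degree=2)
        assert np.abs(out.heights).max() < 1e-9

    def test_plane_plus_sinusoid_residual_by_linearity(self):
        # least squares is linear: residual(plane + wave) == residual(wave),
        # since the plane itself fits exactly
        x, y = np.meshgrid(np.arange(64) * 0.02, np.arange(64) * 0.02, indexing="ij")
        wave = 5.0 * np.sin(2 * np.pi * x / 0.32)
        combined = op.remove_form(self._hm(10 + 4 * x - 2 * y + wave), degree=1)
        wave_only = op.remove_form(self._hm(wave), degree=1)
        assert np.allclose(combined.heights, wave_only.heights, atol=1e-6)
        # and the residual is still dominated by the sinusoid
        assert combined.heights.std() == pytest.approx(wave.std(), rel=0.02)

    def test_constant_absorbed_by_degree_one(self):
        hm = self._hm(np.full((10, 10), 7.5))
        out = op.remove_form(hm, degree=1)
        assert np.abs(out.heights).max() < 1e-9

    def test_residual_mean_is_zero(self, rng):
        hm = self._hm(rng.normal(0, 3, (30, 30)))
        out = op.remove_form(hm, degree=2)
        assert abs(out.heights[out.valid].mean()) < 1e-9


class TestGaussianHighpass:
    def test_constant_surface_gives_zero_roughness(self):
        hm = op.HeightMap(np.full((200, 200), 4.2), 0.02)
        out = op.gaussian_highpass(hm, cutoff_mm=0.8)
        assert np.abs(out.heights[out.valid]).max() < 1e-9

    @staticmethod
    def _sinusoid_response(wavelength_mm, cutoff_mm=0.8, spacing=0.01):
        n = int(round(8 * cutoff_mm / spacing))
        x = np.arange(n) * spacing
        wave = 10.0 * np.sin(2 * np.pi * x / wavelength_mm)
        hm = op.HeightMap(np.tile(wave, (n, 1)), spacing)
        out = op.gaussian_highpass(hm, cutoff_mm)
        keep = out.valid[n // 2]
        xs = x[keep]
        row = out.heights[n // 2][keep]
        # quadrature amplitude fit at the known wavelength
        c = np.cos(2 * np.pi * xs / wavelength_mm)
        s = np.sin(2 * np.pi * xs / wavelength_mm)
        amp = 2 * np.hypot((row * c).mean(), (row * s).mean())
        return amp / 10.0

    def test_fifty_percent_transmission_at_cutoff(self):
        assert self._sinusoid_response(0.8) == pytest.approx(0.5, abs=0.02)

    def test_short_wavelengths_fully_transmitted(self):
        assert self._sinusoid_response(0.1) >= 0.99

    def test_undersized_area_rejected(self):
        hm = op.HeightMap(np.zeros((20, 20)), 0.02)  # 0.38 mm extent
        with pytest.raises(ParameterError):
            op.gaussian_highpass(hm, cutoff_mm=0.8)

    def test_kernel_constant_matches_iso_definition(self):
        assert ALPHA == pytest.approx(np.sqrt(np.log(2) / np.pi))


class TestRoughnessParams:
    def test_null_surface(self):
        hm = op.HeightMap(np.zeros((10, 10)), 0.02)
        r = op.roughness_params(hm)
        assert (r.Sq, r.Sa, r.Sp, r.Sv) == (0.0, 0.0, 0.0, 0.0)

    def test_sinusoid_closed_forms(self):
        A = 10.0
        n = 400
        x = np.arange(n) * 0.01
        wave = A * np.sin(2 * np.pi * x / 0.5)  # 8 full periods
        hm = op.HeightMap(np.tile(wave, (50, 1)), 0.01)
        r = op.roughness_params(hm)
        assert r.Sq == pytest.approx(A / np.sqrt(2), rel=0.005)
        assert r.Sa == pytest.approx(2 * A / np.pi, rel=0.005)
        assert r.Sp == pytest.approx(A, rel=0.005)
        assert r.Sv == pytest.approx(A, rel=0.005)

    def test_negation_swaps_peak_and_pit(self, rng):
        z = rng.normal(0, 2, (20, 20))
        r1 = op.roughness_params(op.HeightMap(z, 0.02))
        r2 = op.roughness_params(op.HeightMap(-z, 0.02))
        assert r1.Sq == pytest.approx(r2.Sq)
        assert r1.Sa == pytest.approx(r2.Sa)
        assert r1.Sp == pytest.approx(r2.Sv)
        assert r1.Sv == pytest.approx(r2.Sp)

    def test_sq_dominates_sa(self, rng):
        for _ in range(10):
            z = rng.normal(0, rng.uniform(0.5, 5), (15, 15))
            r = op.roughness_params(op.HeightMap(z, 0.02))
            assert r.Sq >= r.Sa

    def test_height_offset_invariance_through_pipeline(self, rng):
        base = rng.normal(0, 2, (200, 200))
        for offset in (0.0, 35.0):
            hm = op.HeightMap(base + offset, 0.01)
            hm = op.remove_form(hm, 1)
            hm = op.gaussian_highpass(hm, 0.8)
            r = op.roughness_params(hm)
            if offset == 0.0:
                ref = r
        assert r.Sq == pytest.approx(ref.Sq, abs=1e-9)
        assert r.Sa == pytest.approx(ref.Sa, abs=1e-9)
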