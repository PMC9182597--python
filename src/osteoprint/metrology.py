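"""Geometric verification: best-fit deviation and areal surface texture.

Two measurement families mirror how printed anatomical models are checked:

* **Best-fit deviation** — a measured point cloud is rigidly registered to
  the nominal mesh by iterative closest point (point-to-point, closed-form
  orthogonal update), then signed point-to-surface distances are summarised
  as mean deviation ȳ and sample standard deviation σ (mm).  Positive means
  outside the closed surface.

* **Areal surface texture** — a height map (μm) is detrended by a low-order
  polynomial (form removal), high-pass filtered with the Gaussian areal
  filter whose amplitude transmission is 50% at the cutoff wavelength λc,
  and summarised by the ISO 25178-2 amplitude parameters Sq (rms height),
  Sa (arithmetical mean height), Sp (maximum peak height) and Sv (maximum
  pit depth).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import MeshError, ParameterError, RegistrationError
from .geometry import closest_on_mesh, ray_parity_inside
from .mesh import TriangleMesh
from .mesh_repair import diagnose

#: Gaussian filter constant: 50% amplitude transmission at the cutoff.
ALPHA = math.sqrt(math.log(2.0) / math.pi)


@dataclass
class RigidTransform:
    """Proper rigid motion: ``x -> R @ x + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ParameterError("rotation must be orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ParameterError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class DeviationReport:
    """Signed point-to-surface deviations and their first two moments (mm)."""

    distances: np.ndarray
    mean_deviation: float
    standard_deviation: float
    point_count: int

    def as_dict(self) -> dict:
        return {
            "mean_deviation_mm": self.mean_deviation,
            "standard_deviation_mm": self.standard_deviation,
            "point_count": self.point_count,
        }


@dataclass
class HeightMap:
    """Regular grid of surface heights (μm) with lateral spacing in mm."""

    heights: np.ndarray
    spacing: float
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ParameterError("height map must be 2-D")
        if self.spacing <= 0:
            raise ParameterError("lateral spacing must be positive")
        if self.valid is None:
            self.valid = np.ones(self.heights.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.heights.shape:
                raise ParameterError("valid mask shape mismatch")
        for axis in range(2):
            if (self.valid.any(axis=1 - axis)).sum() < 2:
                raise ParameterError("need >= 2 valid samples per axis")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return tuple((n - 1) * self.spacing for n in self.heights.shape)


@dataclass
class RoughnessReport:
    """ISO 25178-2 amplitude parameters (μm)."""

    Sq: float
    Sa: float
    Sv: float
    Sp: float
    cutoff_mm: float | None = None
    area_mm: tuple[float, float] | None = None

    def as_dict(self) -> dict:
        return {
            "Sq_um": self.Sq,
            "Sa_um": self.Sa,
            "Sv_um": self.Sv,
            "Sp_um": self.Sp,
            "cutoff_mm": self.cutoff_mm,
            "area_mm": list(self.area_mm) if self.area_mm else None,
        }


# ---------------------------------------------------------------------------
# best fit
# ---------------------------------------------------------------------------


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping source onto target."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


def best_fit(
    points: np.ndarray,
    mesh: TriangleMesh,
    tol: float = 0.001,
    max_iter: int = 100,
) -> RigidTransform:
    """Iterative-closest-point rigid registration of points onto a mesh.

    Point-to-point correspondences (nearest point on any triangle) with a
    closed-form orthogonal update each iteration; stops when the RMS
    residual changes by less than ``tol`` mm (default 0.001 mm).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise RegistrationError("best fit needs at least 3 points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise RegistrationError("points are collinear")
    if mesh.is_empty():
        raise RegistrationError("mesh is empty")
    if tol <= 0 or max_iter < 1:
        raise ParameterError("tol must be positive and max_iter >= 1")

    tri = mesh.vertices[mesh.triangles]
    tree = cKDTree(tri.mean(axis=1))

    transform = RigidTransform.identity()
    prev_rms = np.inf
    for _ in range(max_iter):
        moved = transform.apply(points)
        dist, closest, _ = closest_on_mesh(moved, mesh.vertices, mesh.triangles, tree=tree)
        rms = float(np.sqrt(np.mean(dist**2)))
        if abs(prev_rms - rms) < tol:
            return transform
        prev_rms = rms
        transform = _kabsch(points, closest)
    warnings.warn(
        f"best_fit did not converge within {max_iter} iterations (RMS {prev_rms:.6f} mm)",
        stacklevel=2,
    )
    return transform


def deviation_report(
    points: np.ndarray,
    mesh: TriangleMesh,
    transform: RigidTransform | None = None,
    signed: bool = True,
) -> DeviationReport:
    """Signed distances of (transformed) points to the mesh, with ȳ and σ.

    Sign convention: positive outside the closed surface, negative inside
    (containment decided by ray parity).  For an open mesh signed distances
    are undefined; pass ``signed=False`` to get unsigned statistics.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if transform is not None:
        points = transform.apply(points)
    diag = diagnose(mesh)
    if signed:
        if not diag.watertight:
            raise MeshError(
                "mesh is not closed: signed deviation undefined (use signed=False)"
            )
        work = mesh if diag.outward_oriented else TriangleMesh(
            mesh.vertices, mesh.triangles[:, ::-1]
        )
    else:
        warnings.warn("unsigned deviations: sign of ȳ is not meaningful", stacklevel=2)
        work = mesh

    dist, _, _ = closest_on_mesh(points, work.vertices, work.triangles)
    if signed:
        inside = ray_parity_inside(points, work.vertices, work.triangles)
        dist = np.where(inside, -dist, dist)
    n = len(points)
    return DeviationReport(
        distances=dist,
        mean_deviation=float(dist.mean()),
        standard_deviation=float(dist.std(ddof=1)) if n > 1 else 0.0,
        point_count=n,
    )


# ---------------------------------------------------------------------------
# surface texture
# ---------------------------------------------------------------------------


def _poly_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(x), x, y]
    if degree == 2:
        cols += [x * x, x * y, y * y]
    return np.column_stack(cols)


def remove_form(hm: HeightMap, degree: int = 2) -> HeightMap:
    """Subtract a least-squares bivariate polynomial (degree 1 or 2).

    Removes the specimen's shape error so only texture remains; the residual
    mean over valid samples is zero by construction.
    """
    if degree not in (1, 2):
        raise ParameterError("degree must be 1 or 2")
    n_params = 3 if degree == 1 else 6
    if hm.valid.sum() < n_params:
        raise ParameterError("not enough valid samples for the polynomial fit")
    ii, jj = np.indices(hm.heights.shape)
    x = ii * hm.spacing
    y = jj * hm.spacing
    A = _poly_terms(x[hm.valid], y[hm.valid], degree)
    coef, *_ = np.linalg.lstsq(A, hm.heights[hm.valid], rcond=None)
    fit = (_poly_terms(x.ravel(), y.ravel(), degree) @ coef).reshape(hm.heights.shape)
    return HeightMap(hm.heights - fit, hm.spacing, hm.valid.copy())


def gaussian_highpass(hm: HeightMap, cutoff_mm: float = 0.8) -> HeightMap:
    """Separate roughness from waviness with the areal Gaussian filter.

    The weighting function has 50% amplitude transmission at wavelength
    ``cutoff_mm`` (kernel scale α·λc with α = sqrt(ln 2 / π)); the roughness
    surface is the input minus the Gaussian-weighted mean.  A border band of
    λc/2 is marked invalid instead of padding, avoiding end effects.
    """
    if cutoff_mm <= 0:
        raise ParameterError("cutoff must be positive")
    ext = hm.extent_mm
    if any(e < 2 * cutoff_mm for e in ext):
        raise ParameterError(
            f"evaluation area {ext} mm smaller than 2×λc per axis"
        )
    sigma_mm = ALPHA * cutoff_mm / math.sqrt(2.0 * math.pi)
    sigma_px = sigma_mm / hm.spacing
    mean_surface = ndimage.gaussian_filter(hm.heights, sigma=sigma_px, mode="nearest")
    rough = hm.heights - mean_surface

    band = int(math.ceil(0.5 * cutoff_mm / hm.spacing))
    valid = hm.valid.copy()
    valid[:band, :] = False
    valid[-band:, :] = False
    valid[:, :band] = False
    valid[:, -band:] = False
    return HeightMap(rough, hm.spacing, valid)


def roughness_params(
    hm: HeightMap,
    cutoff_mm: float | None = None,
) -> RoughnessReport:
    """Amplitude parameters over the valid samples of a roughness surface.

    Sq = sqrt(mean z²), Sa = mean |z|, Sp = max z, Sv = |min z|; the surface
    is expected to be (near) zero-mean after form removal and filtering.
    """
    if not hm.valid.any():
        raise ParameterError("no valid samples in the height map")
    z = hm.heights[hm.valid]
    return RoughnessReport(
        Sq=float(np.sqrt(np.mean(z**2))),
        Sa=float(np.mean(np.abs(z))),
        Sv=float(abs(z.min())),
        Sp=float(z.max()),
        cutoff_mm=cutoff_mm,
        area_mm=hm.extent_mm,
    )


# ---------------------------------------------------------------------------
# point-cloud text I/O
# ---------------------------------------------------------------------------


def read_xyz(path) -> np.ndarray:
    """Whitespace-delimited XYZ point cloud (mm), comments with '#'."""
    return np.loadtxt(path, comments="#", ndmin=2)[:, :3]


def write_xyz(points: np.ndarray, path) -> None:
    np.savetxt(path, np.atleast_2d(points), fmt="%.6f")
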