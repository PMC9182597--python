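"""Synthetic hip/knee-like CT phantoms with exact analytic ground truth.

The generator rasterises simple solids (spheres, capsules, spherical shells,
boxes) onto a voxel grid at literature-typical Hounsfield values, then
degrades the volume the way a metal-bearing CT acquisition is degraded:
zero-mean Gaussian noise plus streak artifacts radiating from the implant.
Because membership is evaluated analytically at voxel centres, every
downstream stage (enhancement, segmentation, meshing, metrology) can be
verified against known truth without any external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .volume_io import HU_MAX, HU_MIN, BinaryMask, HUVolume

#: Default HU palette: within literature-typical CT ranges.
HU_AIR = -1000.0
HU_SOFT_TISSUE = 40.0
HU_TRABECULAR = 300.0
HU_CORTICAL = 1400.0
HU_CEMENT = 1000.0
HU_METAL = 8000.0


@dataclass
class Primitive:
    """One analytic solid: geometry in mm, its HU value and structure label."""

    shape: str  # sphere | capsule | shell | box
    params: dict
    hu: float
    label: str

    def __post_init__(self):
        if self.shape not in ("sphere", "capsule", "shell", "box"):
            raise ParameterError(f"unknown primitive shape {self.shape!r}")
        if not (HU_MIN <= self.hu <= HU_MAX):
            raise ParameterError("primitive HU outside representable range")
        if self.shape == "shell":
            if self.params["r_outer"] <= self.params["r_inner"]:
                raise ParameterError("shell outer radius must exceed inner radius")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Membership of world points ``(n, 3)`` (mm), evaluated analytically."""
        p = self.params
        if self.shape == "sphere":
            d = pts - np.asarray(p["center"], dtype=float)
            return np.einsum("ij,ij->i", d, d) <= p["radius"] ** 2
        if self.shape == "shell":
            d = pts - np.asarray(p["center"], dtype=float)
            r2 = np.einsum("ij,ij->i", d, d)
            return (r2 <= p["r_outer"] ** 2) & (r2 >= p["r_inner"] ** 2)
        if self.shape == "capsule":
            a = np.asarray(p["p0"], dtype=float)
            b = np.asarray(p["p1"], dtype=float)
            ab = b - a
            denom = float(ab @ ab)
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
            closest = a + np.atleast_1d(t)[:, None] * ab
            d = pts - closest
            return np.einsum("ij,ij->i", d, d) <= p["radius"] ** 2
        # box
        lo = np.asarray(p["lo"], dtype=float)
        hi = np.asarray(p["hi"], dtype=float)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        if self.shape in ("sphere", "shell"):
            r = p["radius"] if self.shape == "sphere" else p["r_outer"]
            c = np.asarray(p["center"], dtype=float)
            return c - r, c + r
        if self.shape == "capsule":
            a = np.asarray(p["p0"], dtype=float)
            b = np.asarray(p["p1"], dtype=float)
            r = p["radius"]
            return np.minimum(a, b) - r, np.maximum(a, b) + r
        return np.asarray(p["lo"], dtype=float), np.asarray(p["hi"], dtype=float)

    def analytic_volume(self) -> float | None:
        """Closed-form solid volume (mm³) where available."""
        p = self.params
        if self.shape == "sphere":
            return 4.0 / 3.0 * math.pi * p["radius"] ** 3
        if self.shape == "capsule":
            L = float(np.linalg.norm(np.asarray(p["p1"]) - np.asarray(p["p0"])))
            r = p["radius"]
            return math.pi * r * r * L + 4.0 / 3.0 * math.pi * r**3
        if self.shape == "box":
            ext = np.asarray(p["hi"], dtype=float) - np.asarray(p["lo"], dtype=float)
            return float(np.prod(ext))
        if self.shape == "shell":
            return 4.0 / 3.0 * math.pi * (p["r_outer"] ** 3 - p["r_inner"] ** 3)
        return None

    def analytic_area(self) -> float | None:
        """Closed-form surface area (mm²) where available."""
        p = self.params
        if self.shape == "sphere":
            return 4.0 * math.pi * p["radius"] ** 2
        if self.shape == "capsule":
            L = float(np.linalg.norm(np.asarray(p["p1"]) - np.asarray(p["p0"])))
            r = p["radius"]
            return 2.0 * math.pi * r * L + 4.0 * math.pi * r * r
        return None


@dataclass
class StreakSpec:
    center: tuple[float, float, float]
    amplitude: float
    count: int = 8
    decay: float = 20.0  # mm


@dataclass
class PhantomSpec:
    """Recipe for a synthetic CT volume: grid, solids, noise and artifacts."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    primitives: list[Primitive] = field(default_factory=list)
    background_hu: float = HU_AIR
    noise_sd: float = 0.0
    streaks: StreakSpec | None = None
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.streaks is not None and self.streaks.count < 0:
            raise ParameterError("streak count must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom.

    ``masks`` maps structure label to the exact voxel-centre membership mask
    (mutually exclusive; the last-listed primitive wins at each voxel);
    ``descriptors`` keeps the analytic solids so truth can be re-rasterised
    on any other grid (e.g. after interpolation).
    """

    masks: dict[str, BinaryMask]
    descriptors: list[Primitive]
    analytic_volumes: dict[str, float]
    analytic_areas: dict[str, float]

    def rasterize(
        self,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> dict[str, BinaryMask]:
        """Exact truth masks on an arbitrary grid (voxel-centre membership)."""
        pts = _grid_points(shape, spacing, origin)
        owner = np.full(pts.shape[0], -1, dtype=np.int32)
        for idx, prim in enumerate(self.descriptors):
            owner[prim.contains(pts)] = idx
        out: dict[str, BinaryMask] = {}
        for label in {p.label for p in self.descriptors}:
            ids = [i for i, p in enumerate(self.descriptors) if p.label == label]
            m = np.isin(owner, ids).reshape(shape).astype(np.uint8)
            out[label] = BinaryMask(m, spacing, origin)
        return out


def _grid_points(shape, spacing, origin) -> np.ndarray:
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gg.ravel() for gg in g])


def generate_phantom(spec: PhantomSpec) -> tuple[HUVolume, PhantomTruth]:
    """Rasterise a phantom spec; returns the degraded volume plus exact truth.

    Voxel HU is the value of the *last-listed* primitive covering the voxel
    centre (no partial-volume antialiasing).  Streaks are applied before
    noise so the noise also rides on the artifact, as on a real scan.
    Deterministic for a given seed.
    """
    shape, spacing, origin = spec.shape, spec.spacing, spec.origin
    extent_lo = np.asarray(origin, dtype=float)
    extent_hi = extent_lo + (np.asarray(shape) - 1) * np.asarray(spacing)
    margin = 2.0 * np.asarray(spacing)
    for prim in spec.primitives:
        lo, hi = prim.bounds()
        if np.any(lo < extent_lo + margin - 1e-9) or np.any(hi > extent_hi - margin + 1e-9):
            raise GeometryError(
                f"primitive {prim.label!r} does not fit in the grid with a 2-voxel margin"
            )

    pts = _grid_points(shape, spacing, origin)
    values = np.full(pts.shape[0], float(spec.background_hu))
    owner = np.full(pts.shape[0], -1, dtype=np.int32)
    for idx, prim in enumerate(spec.primitives):
        m = prim.contains(pts)
        values[m] = prim.hu
        owner[m] = idx

    masks: dict[str, BinaryMask] = {}
    vols: dict[str, float] = {}
    areas: dict[str, float] = {}
    for label in {p.label for p in spec.primitives}:
        ids = [i for i, p in enumerate(spec.primitives) if p.label == label]
        m = np.isin(owner, ids).reshape(shape).astype(np.uint8)
        masks[label] = BinaryMask(m, spacing, origin)
        v = [spec.primitives[i].analytic_volume() for i in ids]
        if all(x is not None for x in v):
            vols[label] = float(sum(v))
        a = [spec.primitives[i].analytic_area() for i in ids]
        if all(x is not None for x in a):
            areas[label] = float(sum(a))

    vol = HUVolume(values.reshape(shape), spacing, origin)
    truth = PhantomTruth(masks, list(spec.primitives), vols, areas)

    if spec.streaks is not None and spec.streaks.amplitude != 0 and spec.streaks.count > 0:
        vol = add_streaks(
            vol,
            spec.streaks.center,
            spec.streaks.amplitude,
            spec.streaks.count,
            spec.streaks.decay,
            seed=spec.seed,
        )
    if spec.noise_sd > 0:
        vol = add_noise(vol, spec.noise_sd, seed=spec.seed + 1)
    return vol, truth


def add_noise(vol: HUVolume, sd: float, seed: int) -> HUVolume:
    """Add zero-mean Gaussian noise (HU), clipped to the representable range."""
    if sd < 0:
        raise ParameterError("noise sd must be non-negative")
    if sd == 0:
        return vol.with_values(vol.values.copy())
    rng = np.random.default_rng(seed)
    noisy = vol.values + rng.normal(0.0, sd, size=vol.shape)
    return vol.with_values(np.clip(noisy, HU_MIN, HU_MAX))


def add_streaks(
    vol: HUVolume,
    center: tuple[float, float, float],
    amplitude: float,
    count: int,
    decay: float,
    seed: int,
) -> HUVolume:
    """Metal-streak stand-in: alternating ± spokes radiating from ``center``.

    Within each slice the perturbation is ``amplitude * cos(count * (phi -
    phi0)) * exp(-d / decay)`` where ``(d, phi)`` are polar coordinates about
    the in-plane projection of ``center``.  The alternating sign makes the
    slice mean of the artifact nearly zero, and the magnitude decays
    exponentially with distance, mimicking the bright/dark spokes seen around
    implants.  Not a physical beam-hardening model.
    """
    if count < 1:
        raise ParameterError("streak count must be >= 1")
    if decay <= 0:
        raise ParameterError("streak decay length must be positive")
    if amplitude < 0:
        raise ParameterError("streak amplitude must be non-negative")
    if amplitude == 0:
        return vol.with_values(vol.values.copy())

    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    rows, cols, _ = vol.shape
    r_mm = vol.origin[0] + np.arange(rows) * vol.spacing[0] - center[0]
    c_mm = vol.origin[1] + np.arange(cols) * vol.spacing[1] - center[1]
    R, C = np.meshgrid(r_mm, c_mm, indexing="ij")
    d = np.hypot(R, C)
    phi = np.arctan2(C, R)
    pattern = amplitude * np.cos(count * (phi - phi0)) * np.exp(-d / decay)
    out = vol.values + pattern[:, :, None]
    return vol.with_values(np.clip(out, HU_MIN, HU_MAX))


def sphere_distance_volume(
    radius: float,
    spacing: float,
    center: tuple[float, float, float] | None = None,
    pad_mm: float = 3.0,
) -> HUVolume:
    """Signed-distance field of a ball sampled on a grid (positive inside).

    Marching cubes at iso 0 on this field recovers the sphere with linear
    sub-voxel accuracy, which is how the mesh-accuracy convergence checks are
    driven.  Values are a geometric field, not Hounsfield units, but reuse the
    volume container for its grid bookkeeping.
    """
    n = int(math.ceil(2 * (radius + pad_mm) / spacing)) + 1
    if center is None:
        c = (n - 1) / 2.0 * spacing
        center = (c, c, c)
    ax = [np.arange(n) * spacing - center[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    dist = radius - np.sqrt(X * X + Y * Y + Z * Z)
    return HUVolume(np.clip(dist, HU_MIN, HU_MAX), (spacing,) * 3)


def box_distance_volume(
    half_extents: tuple[float, float, float],
    spacing: float,
    pad_mm: float = 3.0,
) -> HUVolume:
    """Signed-distance field of an axis-aligned box (positive inside)."""
    h = np.asarray(half_extents, dtype=float)
    n = [int(math.ceil(2 * (hh + pad_mm) / spacing)) + 1 for hh in h]
    ax = [np.arange(m) * spacing - (m - 1) / 2.0 * spacing for m in n]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    qx, qy, qz = np.abs(X) - h[0], np.abs(Y) - h[1], np.abs(Z) - h[2]
    outside = np.sqrt(
        np.maximum(qx, 0) ** 2 + np.maximum(qy, 0) ** 2 + np.maximum(qz, 0) ** 2
    )
    inside = np.minimum(np.maximum(qx, np.maximum(qy, qz)), 0.0)
    return HUVolume(np.clip(-(outside + inside), HU_MIN, HU_MAX), (spacing,) * 3)


def capsule_distance_volume(
    length: float,
    radius: float,
    spacing: float,
    pad_mm: float = 3.0,
) -> HUVolume:
    """Signed-distance field of a z-aligned capsule (positive inside)."""
    nxy = int(math.ceil(2 * (radius + pad_mm) / spacing)) + 1
    nz = int(math.ceil((length + 2 * (radius + pad_mm)) / spacing)) + 1
    ax = np.arange(nxy) * spacing - (nxy - 1) / 2.0 * spacing
    az = np.arange(nz) * spacing - (nz - 1) / 2.0 * spacing
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    zc = np.clip(Z, -length / 2.0, length / 2.0)
    dist = radius - np.sqrt(X * X + Y * Y + (Z - zc) ** 2)
    return HUVolume(np.clip(dist, HU_MIN, HU_MAX), (spacing,) * 3)


def femur_implant_phantom(
    shape: tuple[int, int, int] = (80, 80, 36),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5),
    noise_sd: float = 0.0,
    streak_amplitude: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """The standard study phantom: femur-like bone with an intramedullary nail.

    Soft-tissue block, cortical capsule shell around a trabecular core, a
    spherical "femoral head", a metal nail (capsule) down the shaft and a
    cement sleeve around the nail — the image content the procedure is built
    to process.  Streaks radiate from the nail axis when enabled.
    """
    ext = (np.asarray(shape) - 1) * np.asarray(spacing)
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    z0, z1 = 18.0, 35.0  # shaft axis endpoints (mm)
    prims = [
        Primitive(
            "box",
            {"lo": (4.0, 4.0, 4.0), "hi": tuple(ext - 4.0)},
            HU_SOFT_TISSUE,
            "soft_tissue",
        ),
        # cortical sheath: outer capsule overwritten by the trabecular core
        Primitive(
            "capsule",
            {"p0": (cx, cy, z0), "p1": (cx, cy, z1), "radius": 14.0},
            HU_CORTICAL,
            "bone",
        ),
        Primitive(
            "capsule",
            {"p0": (cx, cy, z0), "p1": (cx, cy, z1), "radius": 10.5},
            HU_TRABECULAR,
            "bone",
        ),
        Primitive("sphere", {"center": (cx, cy, z1), "radius": 12.0}, HU_CORTICAL, "bone"),
        Primitive(
            "capsule",
            {"p0": (cx, cy, z0 + 4.0), "p1": (cx, cy, z1 - 6.0), "radius": 5.0},
            HU_CEMENT,
            "bone_cement",
        ),
        Primitive(
            "capsule",
            {"p0": (cx, cy, z0 + 6.0), "p1": (cx, cy, z1 - 8.0), "radius": 3.0},
            HU_METAL,
            "implant",
        ),
    ]
    streaks = None
    if streak_amplitude > 0:
        streaks = StreakSpec(center=(cx, cy, 0.0), amplitude=streak_amplitude, count=10, decay=25.0)
    return PhantomSpec(
        shape=tuple(shape),
        spacing=tuple(spacing),
        primitives=prims,
        noise_sd=noise_sd,
        streaks=streaks,
        seed=seed,
    )
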