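"""Bone / implant / cement segmentation by thresholds and region growing.

Region growing is flood fill from seed voxels through neighbours whose HU
lies inside a closed interval; local thresholding applies different
intervals inside different axis-aligned boxes of one volume.  Per-case
thresholds can be averaged into reusable presets (mean ± sd over cases).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .errors import LabelCollisionError, ParameterError
from .volume_io import BinaryMask, HUVolume, LabelVolume


@dataclass
class ThresholdEntry:
    """Averaged segmentation interval for one structure (HU)."""

    low: float
    high: float
    sd_low: float = 0.0
    sd_high: float = 0.0
    n_cases: int = 1

    def __post_init__(self):
        if self.low > self.high:
            raise ParameterError("low threshold exceeds high threshold")
        if self.sd_low < 0 or self.sd_high < 0:
            raise ParameterError("threshold sd must be non-negative")
        if self.n_cases < 1:
            raise ParameterError("n_cases must be >= 1")


@dataclass
class ThresholdPreset:
    """Per-structure averaged HU segmentation thresholds."""

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {
            name: {
                "low": float(e.low),
                "high": float(e.high),
                "sd_low": float(e.sd_low),
                "sd_high": float(e.sd_high),
                "n": int(e.n_cases),
            }
            for name, e in self.entries.items()
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdPreset":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            {
                name: ThresholdEntry(
                    d["low"], d["high"], d.get("sd_low", 0.0), d.get("sd_high", 0.0), d.get("n", 1)
                )
                for name, d in doc.items()
            }
        )


@dataclass
class LocalRegion:
    """An axis-aligned voxel box with its own HU interval and seeds.

    ``roi`` is ((i0, j0, k0), (i1, j1, k1)) with an inclusive lower corner
    and exclusive upper corner; seeds are absolute voxel indices inside it.
    """

    roi: tuple[tuple[int, int, int], tuple[int, int, int]]
    low: float
    high: float
    seeds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.roi
        if any(h <= l for l, h in zip(lo, hi)):
            raise ParameterError("roi upper corner must exceed lower corner")
        if self.low > self.high:
            raise ParameterError("low threshold exceeds high threshold")
        for s in self.seeds:
            if not all(l <= si < h for si, l, h in zip(s, lo, hi)):
                raise ParameterError(f"seed {s} outside roi {self.roi}")


def threshold_mask(vol: HUVolume, low: float, high: float) -> BinaryMask:
    """Closed-interval threshold: mask = 1 where low <= value <= high."""
    if low > high:
        raise ParameterError("low threshold exceeds high threshold")
    m = ((vol.values >= low) & (vol.values <= high)).astype(np.uint8)
    return BinaryMask(m, vol.spacing, vol.origin)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ParameterError("connectivity must be 6 or 26")


def region_grow(
    vol: HUVolume,
    seeds: list[tuple[int, int, int]],
    low: float,
    high: float,
    connectivity: int = 26,
) -> BinaryMask:
    """Flood fill from seeds through connectivity-adjacent in-range voxels.

    Seeds whose value falls outside [low, high] are rejected with a warning;
    with no accepted seed the result is an empty mask (warning), not an
    error.  The result is always a subset of the plain threshold mask.
    """
    if low > high:
        raise ParameterError("low threshold exceeds high threshold")
    struct = _structure(connectivity)
    in_range = (vol.values >= low) & (vol.values <= high)

    accepted = []
    for s in seeds:
        s = tuple(int(x) for x in s)
        if not all(0 <= si < n for si, n in zip(s, vol.shape)):
            raise ParameterError(f"seed {s} outside the grid")
        if in_range[s]:
            accepted.append(s)
        else:
            warnings.warn(f"seed {s} outside [{low}, {high}]; rejected", stacklevel=2)

    if not accepted:
        warnings.warn("no accepted seed; returning empty mask", stacklevel=2)
        return BinaryMask(
            np.zeros(vol.shape, dtype=np.uint8), vol.spacing, vol.origin
        )

    labels, _ = ndimage.label(in_range, structure=struct)
    wanted = {int(labels[s]) for s in accepted} - {0}
    mask = np.isin(labels, sorted(wanted)).astype(np.uint8)
    return BinaryMask(mask, vol.spacing, vol.origin)


def segment_local(
    vol: HUVolume,
    regions: list[LocalRegion],
    labels: list[str],
    connectivity: int = 26,
) -> LabelVolume:
    """Grow each region inside its own box; earlier regions win overlaps."""
    if len(regions) != len(labels):
        raise ParameterError("regions and labels must have the same length")
    if len(set(labels)) != len(labels):
        raise LabelCollisionError("duplicate structure names in labels")

    out = np.zeros(vol.shape, dtype=np.int16)
    legend: dict[int, str] = {}
    for idx, (region, name) in enumerate(zip(regions, labels), start=1):
        lo, hi = region.roi
        for l, h, n in zip(lo, hi, vol.shape):
            if l < 0 or h > n:
                raise ParameterError(f"roi {region.roi} outside the grid")
        sub = HUVolume(
            vol.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]],
            vol.spacing,
            tuple(vol.origin[a] + lo[a] * vol.spacing[a] for a in range(3)),
        )
        local_seeds = [tuple(s[a] - lo[a] for a in range(3)) for s in region.seeds]
        if not local_seeds:
            warnings.warn(f"region {name!r} has no seeds; contributes nothing", stacklevel=2)
            legend[idx] = name
            continue
        grown = region_grow(sub, local_seeds, region.low, region.high, connectivity)
        target = out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        claim = grown.astype_bool() & (target == 0)
        target[claim] = idx
        legend[idx] = name
    return LabelVolume(out, legend, vol.spacing, vol.origin)


def separate_implant(
    vol: HUVolume,
    bone: tuple[float, float],
    metal_low: float,
    margin: float = 0.5,
    keep: str = "largest",
    bone_seeds: list[tuple[int, int, int]] | None = None,
    connectivity: int = 26,
) -> tuple[BinaryMask, BinaryMask]:
    """Split metal from bone: high threshold for metal, margin-dilated subtraction.

    The implant is the largest connected component at or above ``metal_low``
    (``keep="all"`` retains every metal component, for multi-implant cases).
    The bone mask is the bone-interval mask (region-grown when seeds are
    given) minus the implant dilated by ``margin`` mm, suppressing the
    blooming halo at metal boundaries.  The two masks never overlap.
    """
    bone_low, bone_high = bone
    if metal_low <= bone_high:
        raise ParameterError("metal_low must exceed the bone interval's high end")
    if margin < 0:
        raise ParameterError("margin must be non-negative")

    metal = vol.values >= metal_low
    if not metal.any():
        implant_arr = np.zeros(vol.shape, dtype=np.uint8)
    elif keep == "all":
        implant_arr = metal.astype(np.uint8)
    else:
        labels, n = ndimage.label(metal, structure=_structure(connectivity))
        sizes = ndimage.sum_labels(metal, labels, index=np.arange(1, n + 1))
        implant_arr = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)

    if bone_seeds:
        bone_mask = region_grow(vol, bone_seeds, bone_low, bone_high, connectivity)
        bone_arr = bone_mask.astype_bool()
    else:
        bone_arr = (vol.values >= bone_low) & (vol.values <= bone_high)

    if implant_arr.any() and margin > 0:
        dist = ndimage.distance_transform_edt(implant_arr == 0, sampling=vol.spacing)
        dilated = dist <= margin
    else:
        dilated = implant_arr.astype(bool)

    bone_arr = bone_arr & ~dilated
    return (
        BinaryMask(bone_arr.astype(np.uint8), vol.spacing, vol.origin),
        BinaryMask(implant_arr, vol.spacing, vol.origin),
    )


def average_thresholds(cases: list[dict[str, tuple[float, float]]]) -> ThresholdPreset:
    """Average per-case (low, high) intervals into a preset.

    Low/high are arithmetic means over the cases naming the structure; the
    spread is the sample standard deviation (n-1 denominator, 0 for a single
    case).
    """
    if not cases:
        raise ParameterError("at least one case is required")
    names = sorted({name for case in cases for name in case})
    entries: dict[str, ThresholdEntry] = {}
    for name in names:
        lows = np.array([case[name][0] for case in cases if name in case], dtype=float)
        highs = np.array([case[name][1] for case in cases if name in case], dtype=float)
        n = len(lows)
        entries[name] = ThresholdEntry(
            low=float(lows.mean()),
            high=float(highs.mean()),
            sd_low=float(lows.std(ddof=1)) if n > 1 else 0.0,
            sd_high=float(highs.std(ddof=1)) if n > 1 else 0.0,
            n_cases=n,
        )
    return ThresholdPreset(entries)


#: Interval presets matching the phantom HU palette (see phantoms module).
PHANTOM_PRESET = ThresholdPreset(
    {
        "bone": ThresholdEntry(150.0, 2500.0),
        "bone_cement": ThresholdEntry(800.0, 1200.0),
        "implant": ThresholdEntry(3000.0, 32767.0),
        "soft_tissue": ThresholdEntry(-200.0, 150.0),
    }
)
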