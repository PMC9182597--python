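"""CT volume containers and DICOM/NIfTI input-output.

Grid convention used throughout the package
-------------------------------------------
Arrays are indexed ``(row, column, slice)``.  Voxel indices address voxel
*centres* and are 0-based; the world position of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` in millimetres.  Slices are stored (and
written) in ascending order along the slice axis.  Orientation handling
beyond axis-aligned ascending slices is deliberately out of scope.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import (
    InvalidMetadataError,
    MixedSeriesError,
    ParameterError,
    SpacingError,
)

log = logging.getLogger(__name__)

#: Valid range of the Hounsfield scale as carried by this package.
HU_MIN = -1100.0
HU_MAX = 32767.0


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(3)
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class HUVolume:
    """A 3-D scalar grid of Hounsfield units with voxel spacing and origin."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if self.values.ndim != 3:
            raise ParameterError("volume must be 3-D")
        if any(n < 2 for n in self.values.shape):
            raise ParameterError("volume needs at least 2 samples per axis")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("volume contains non-finite values")
        lo, hi = self.values.min(), self.values.max()
        if lo < HU_MIN or hi > HU_MAX:
            raise ParameterError(
                f"values outside the HU range [{HU_MIN}, {HU_MAX}]: [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres, one 1-D array per axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def with_values(self, values: np.ndarray) -> "HUVolume":
        return HUVolume(values, self.spacing, self.origin)


@dataclass
class BinaryMask:
    """Per-voxel membership grid over {0, 1}, on the same lattice as a volume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.dtype != np.uint8:
            if not np.isin(np.unique(self.values), (0, 1)).all():
                raise ParameterError("mask values must be 0 or 1")
            self.values = self.values.astype(np.uint8)
        if self.values.ndim != 3:
            raise ParameterError("mask must be 3-D")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)

    @property
    def shape(self):
        return self.values.shape

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class LabelVolume:
    """Mutually exclusive integer structure labels; 0 is background."""

    values: np.ndarray
    legend: dict[int, str]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(np.int16)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        present = set(int(v) for v in np.unique(self.values)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ParameterError(f"labels without legend entry: {sorted(missing)}")
        if self.values.min() < 0:
            raise ParameterError("labels must be non-negative")

    def mask(self, label: int | str) -> BinaryMask:
        if isinstance(label, str):
            rev = {v: k for k, v in self.legend.items()}
            label = rev[label]
        return BinaryMask(
            (self.values == label).astype(np.uint8), self.spacing, self.origin
        )


def apply_rescale(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Convert stored pixel values to Hounsfield units: ``stored*slope + intercept``."""
    if slope == 0:
        raise InvalidMetadataError("rescale slope must be non-zero")
    return np.asarray(stored, dtype=float) * float(slope) + float(intercept)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _choose_representation(values: np.ndarray) -> tuple[float, float]:
    """Pick (slope, intercept) so the rounded stored ints fit int16.

    Slope 1, intercept -1024 is lossless for the ordinary CT range; fall back
    to intercept 0 and finally to a coarser slope for extreme values.
    """
    lo, hi = float(values.min()), float(values.max())
    for slope, intercept in ((1.0, -1024.0), (1.0, 0.0)):
        if -32768 <= (lo - intercept) / slope and (hi - intercept) / slope <= 32767:
            return slope, intercept
    slope = (hi - lo) / 65000.0
    intercept = (hi + lo) / 2.0
    return slope, intercept


def write_dicom_series(vol: HUVolume, path: str | Path) -> list[Path]:
    """Write one single-frame CT slice file per slice of ``vol``.

    Stores enough metadata (Rows/Columns, PixelSpacing, ImagePositionPatient,
    rescale slope/intercept) for :func:`read_dicom_series` to reconstruct the
    volume exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    slope, intercept = _choose_representation(vol.values)
    # UIDs derived from the volume content: deterministic for reruns of the
    # same data, distinct between different series
    import hashlib

    digest = hashlib.sha256(
        vol.values.tobytes()
        + np.asarray(vol.spacing).tobytes()
        + np.asarray(vol.origin).tobytes()
    ).hexdigest()
    series_uid = generate_uid(entropy_srcs=[digest, "series"])
    study_uid = generate_uid(entropy_srcs=[digest, "study"])
    rows, cols, nslices = vol.shape
    written = []
    for k in range(nslices):
        stored = np.round((vol.values[:, :, k] - intercept) / slope).astype(np.int16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[digest, f"slice-{k}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientName = "synthetic^phantom"
        ds.PatientID = "OSTEOPRINT"
        ds.InstanceNumber = k + 1
        ds.Rows = rows
        ds.Columns = cols
        ds.PixelSpacing = [str(vol.spacing[0]), str(vol.spacing[1])]
        ds.SliceThickness = str(vol.spacing[2])
        ds.SpacingBetweenSlices = str(vol.spacing[2])
        ds.ImagePositionPatient = [
            str(vol.origin[0]),
            str(vol.origin[1]),
            str(vol.origin[2] + k * vol.spacing[2]),
        ]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.RescaleSlope = str(slope)
        ds.RescaleIntercept = str(intercept)
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = stored.tobytes()

        fn = path / f"slice_{k:04d}.dcm"
        ds.save_as(fn, enforce_file_format=True)
        written.append(fn)
    return written


def read_dicom_series(path: str | Path) -> HUVolume:
    """Read a directory of single-frame CT slices into an :class:`HUVolume`.

    Slices are sorted by position along the slice axis regardless of file
    naming; rescale slope/intercept are applied (defaulting to 1/0 with a
    warning when absent).
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(f))
        except pydicom.errors.InvalidDicomError:
            continue
    if len(datasets) < 2:
        raise InvalidMetadataError(f"need at least 2 DICOM slices in {path}")

    series = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    if len(series) > 1:
        raise MixedSeriesError(f"directory {path} holds {len(series)} series")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    pixel_spacings = {tuple(float(x) for x in ds.PixelSpacing) for ds in datasets}
    if len(shapes) > 1 or len(pixel_spacings) > 1:
        raise InvalidMetadataError("inconsistent slice dimensions or pixel spacing")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    dz = np.diff(zs)
    if np.any(dz <= 0):
        raise SpacingError("duplicate or non-increasing slice positions")
    if (dz.max() - dz.min()) / dz.mean() > 0.01:
        raise SpacingError("non-uniform inter-slice distance beyond 1%")

    slices = []
    for ds in datasets:
        if hasattr(ds, "RescaleSlope") and hasattr(ds, "RescaleIntercept"):
            slope, intercept = float(ds.RescaleSlope), float(ds.RescaleIntercept)
        else:
            slope, intercept = 1.0, 0.0
            warnings.warn(
                "missing rescale tags; assuming slope 1, intercept 0", stacklevel=2
            )
        slices.append(apply_rescale(ds.pixel_array, slope, intercept))

    values = np.stack(slices, axis=-1)
    row_sp, col_sp = pixel_spacings.pop()
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(zs[0]))
    return HUVolume(values, (row_sp, col_sp, float(dz.mean())), origin)


# ---------------------------------------------------------------------------
# NIfTI masks / labels
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_nifti(obj: BinaryMask | LabelVolume, path: str | Path) -> Path:
    """Export a mask or label volume as NIfTI (values stored as small ints)."""
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(obj.values, dtype=np.int16), _affine(obj.spacing, obj.origin)
    )
    nib.save(img, path)
    if isinstance(obj, LabelVolume):
        import json

        sidecar = path.with_suffix("").with_suffix(".labels.json")
        sidecar.write_text(
            json.dumps({str(k): v for k, v in obj.legend.items()}, indent=1, sort_keys=True)
        )
    return path


def read_nifti_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return BinaryMask((data > 0).astype(np.uint8), spacing, origin)
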