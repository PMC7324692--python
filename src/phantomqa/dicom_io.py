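"""Read and write single-frame CT DICOM series as calibrated HU volumes.

A series folder (one file per slice) is assembled into a single 3D array of
Hounsfield units.  Slices are ordered by ascending ``InstanceNumber`` — the
same rule clinical export uses — with a fall-back to slice position when the
tag is absent.  Stored pixel values are converted to HU through the rescale
slope/intercept tags.

Axis convention (used everywhere in this package):

* axis 0 (slice) — longitudinal ``y``; slice ``i`` is centred at
  ``(i + 0.5) * slice_thickness`` mm from the start of the scan,
* axis 1 (row)   — vertical ``z``,
* axis 2 (col)   — lateral ``x``.

In-plane mm coordinates are measured from the image centre; see
:meth:`Volume.x_mm` / :meth:`Volume.z_mm`.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian

from .errors import (
    DuplicateSliceError,
    InconsistentGeometryError,
    MultipleSeriesError,
    NoDicomFoundError,
)

#: Valid HU range: air at the bottom of the scale up to the densest fiducial.
HU_MIN = -1024.0
HU_MAX = 4000.0

_UID_ROOT = "1.2.826.0.1.3680043.10.1463."


@dataclass(frozen=True)
class SeriesMeta:
    """Geometry and calibration metadata shared by all slices of a series."""

    pixel_spacing_mm: tuple[float, float]  # (row, col)
    slice_thickness_mm: float
    n_slices: int
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0
    series_uid: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_spacing_mm[0] > 0 and self.pixel_spacing_mm[1] > 0):
            raise ValueError("pixel spacing components must be positive")
        if not self.slice_thickness_mm > 0:
            raise ValueError("slice thickness must be positive")
        if self.n_slices < 1:
            raise ValueError("a series needs at least one slice")


@dataclass
class Volume:
    """A calibrated HU volume with its acquisition geometry.

    ``hu`` is indexed ``(slice, row, col)`` and holds Hounsfield units in
    ``[-1024, 4000]``.
    """

    hu: np.ndarray
    meta: SeriesMeta

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("hu must be a 3D (slice, row, col) array")
        if self.hu.shape[0] != self.meta.n_slices:
            raise ValueError(
                f"hu has {self.hu.shape[0]} slices but meta says {self.meta.n_slices}"
            )

    def validate(self) -> None:
        """Check the HU-range and finiteness invariants."""
        if not np.isfinite(self.hu).all():
            raise ValueError("volume contains non-finite HU values")
        lo, hi = float(self.hu.min()), float(self.hu.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU values [{lo}, {hi}] outside [{HU_MIN}, {HU_MAX}]")

    # -- coordinate helpers ------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.hu.shape[0]

    @property
    def slice_thickness_mm(self) -> float:
        return self.meta.slice_thickness_mm

    def x_mm(self) -> np.ndarray:
        """Lateral pixel-centre coordinates (mm from image centre), per column."""
        n = self.hu.shape[2]
        return (np.arange(n) - (n - 1) / 2.0) * self.meta.pixel_spacing_mm[1]

    def z_mm(self) -> np.ndarray:
        """Vertical pixel-centre coordinates (mm from image centre), per row."""
        n = self.hu.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.meta.pixel_spacing_mm[0]

    def y_mm(self) -> np.ndarray:
        """Longitudinal slice-centre coordinates (mm from scan start)."""
        return (np.arange(self.n_slices) + 0.5) * self.meta.slice_thickness_mm

    def copy(self) -> "Volume":
        return Volume(self.hu.copy(), self.meta)


def _slice_sort_key(ds: pydicom.Dataset):
    return int(ds.InstanceNumber)


def read_series(folder_path) -> Volume:
    """Read one DICOM series folder into a :class:`Volume`.

    Files are discovered in arbitrary listing order; the result is invariant
    under any permutation of file names because slices are ordered by
    ``InstanceNumber`` (falling back to slice position with a warning when
    the tag is missing).
    """
    folder = Path(folder_path)
    datasets: list[pydicom.Dataset] = []
    for path in sorted(folder.iterdir()) if folder.is_dir() else []:
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError, ValueError):
            continue
        if "PixelData" not in ds:
            continue
        ds._source_path = str(path)  # for error messages
        datasets.append(ds)
    if not datasets:
        raise NoDicomFoundError(f"no DICOM image files found in {folder}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "")) for ds in datasets}
    uids.discard("")
    if len(uids) > 1:
        raise MultipleSeriesError(
            f"folder {folder} mixes {len(uids)} series: {sorted(uids)}"
        )
    series_uid = next(iter(uids)) if uids else ""

    geometries = {
        (
            tuple(float(v) for v in ds.PixelSpacing),
            float(ds.SliceThickness),
            int(ds.Rows),
            int(ds.Columns),
        )
        for ds in datasets
    }
    if len(geometries) > 1:
        raise InconsistentGeometryError(
            f"inconsistent PixelSpacing/SliceThickness/matrix across slices: {geometries}"
        )
    (spacing, thickness, n_rows, n_cols) = next(iter(geometries))

    if all("InstanceNumber" in ds for ds in datasets):
        datasets.sort(key=_slice_sort_key)
        numbers = [int(ds.InstanceNumber) for ds in datasets]
        if len(set(numbers)) != len(numbers):
            dupes = sorted({n for n in numbers if numbers.count(n) > 1})
            raise DuplicateSliceError(f"duplicate InstanceNumber(s): {dupes}")
        if numbers != list(range(numbers[0], numbers[0] + len(numbers))):
            warnings.warn(
                "InstanceNumber sequence is gapped or does not start at 1; "
                "sorting and proceeding",
                stacklevel=2,
            )
    else:
        warnings.warn(
            "InstanceNumber missing on some slices; ordering by slice position",
            stacklevel=2,
        )

        def _pos(ds):
            if "ImagePositionPatient" in ds:
                return float(ds.ImagePositionPatient[2])
            return float(getattr(ds, "SliceLocation", 0.0))

        datasets.sort(key=_pos)

    slopes_intercepts = set()
    hu = np.empty((len(datasets), n_rows, n_cols), dtype=np.float32)
    for i, ds in enumerate(datasets):
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            warnings.warn(
                f"missing rescale tags in {getattr(ds, '_source_path', '?')}; "
                "assuming slope 1, intercept 0",
                stacklevel=2,
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slopes_intercepts.add((slope, intercept))
        hu[i] = ds.pixel_array.astype(np.float32) * slope + intercept

    slope, intercept = next(iter(slopes_intercepts))
    if len(slopes_intercepts) > 1:
        # Per-slice calibration is legal DICOM; the HU array is already
        # calibrated, so only the recorded meta is approximate.
        slope, intercept = 1.0, 0.0

    meta = SeriesMeta(
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        n_slices=len(datasets),
        rescale_slope=slope,
        rescale_intercept=intercept,
        series_uid=series_uid,
    )
    vol = Volume(hu, meta)
    vol.validate()
    return vol


def _deterministic_uid(tag: str) -> str:
    digest = hashlib.sha1(tag.encode()).hexdigest()
    return (_UID_ROOT + str(int(digest[:16], 16)))[:64]


def write_series(volume: Volume, folder_path, clip: bool = False) -> list[Path]:
    """Write a :class:`Volume` as one DICOM CT file per slice.

    Stored values are ``(hu - intercept) / slope`` as signed 16-bit integers,
    so ``read_series(write_series(v))`` reproduces the HU array exactly.
    Non-integral stored values raise ``ValueError``; values outside the
    int16 range raise unless ``clip=True`` (never a silent wraparound).
    """
    folder = Path(folder_path)
    folder.mkdir(parents=True, exist_ok=True)
    meta = volume.meta
    stored = (np.asarray(volume.hu, dtype=np.float64) - meta.rescale_intercept) / (
        meta.rescale_slope or 1.0
    )
    rounded = np.rint(stored)
    if np.abs(stored - rounded).max() > 1e-6:
        raise ValueError(
            "HU values are not representable as integer stored values under the "
            "series rescale; quantize the volume first"
        )
    if rounded.min() < -32768 or rounded.max() > 32767:
        if clip:
            rounded = np.clip(rounded, -32768, 32767)
        else:
            raise ValueError(
                f"stored values [{rounded.min()}, {rounded.max()}] exceed int16; "
                "pass clip=True to clamp"
            )
    stored_i16 = rounded.astype(np.int16)

    series_uid = meta.series_uid or _deterministic_uid(
        f"series/{meta.n_slices}/{meta.pixel_spacing_mm}/{meta.slice_thickness_mm}"
    )
    n_rows, n_cols = volume.hu.shape[1], volume.hu.shape[2]
    paths: list[Path] = []
    for i in range(volume.n_slices):
        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = CTImageStorage
        file_meta.MediaStorageSOPInstanceUID = _deterministic_uid(f"{series_uid}/{i}")
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=file_meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = _deterministic_uid(f"{series_uid}/study")
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.Rows = n_rows
        ds.Columns = n_cols
        ds.PixelSpacing = [meta.pixel_spacing_mm[0], meta.pixel_spacing_mm[1]]
        ds.SliceThickness = meta.slice_thickness_mm
        ds.ImagePositionPatient = [0.0, 0.0, (i + 0.5) * meta.slice_thickness_mm]
        ds.RescaleSlope = meta.rescale_slope
        ds.RescaleIntercept = meta.rescale_intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.PixelData = stored_i16[i].tobytes()
        path = folder / f"slice_{i + 1:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def with_meta(volume: Volume, **changes) -> Volume:
    """Return a copy of ``volume`` with selected SeriesMeta fields replaced."""
    return Volume(volume.hu, replace(volume.meta, **changes))
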