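"""Uniformity, noise and contrast analyses on automatically selected slices.

All three tests run on circular ROIs whose membership rule is fixed
package-wide: a pixel belongs to an ROI when its centre lies within the ROI
radius (inclusive).  Means are plain averages; sigma is the sample standard
deviation (n-1 denominator) — the sigma_CT image-noise metric.

Slice selection is anchored on the marker-defined middle slice:

* uniformity/noise slice: 10 mm from the middle slice, on the side away
  from the plug-bearing region (the side whose slices have the lower mean
  in-body sigma),
* contrast slice: 50 mm from the middle slice toward the plug side.

Contrast grading matches each measured plug HU to the closest baseline
value via a minimum-total-deviation one-to-one assignment (plug position is
deliberately ignored), then grades |measured - baseline| against a per-plug
tolerance: 30 HU for water-like plugs (|baseline| <= 100 HU), 50 HU
otherwise, both user-overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .dicom_io import Volume
from .errors import RoiError, SliceOutOfRangeError
from .phantom_geometry import DEFAULT_BODY_THRESHOLD_HU, MarkerSet

DEFAULT_ROI_DIAMETER_MM = 10.0
DEFAULT_BIG_ROI_DIAMETER_MM = 60.0
DEFAULT_PERIPHERY_RADIUS_MM = 105.0
DEFAULT_UNIFORM_OFFSET_MM = 10.0
DEFAULT_CONTRAST_OFFSET_MM = 50.0
#: Plug-side detection examines slices up to this far from the middle slice.
PLUG_SIDE_PROBE_MM = 50.0
#: Water-like / dense split for the default 30 / 50 HU contrast tolerances.
WATER_LIKE_LIMIT_HU = 100.0
DEFAULT_CONTRAST_TOLERANCES_HU = (30.0, 50.0)
MIN_ROI_PIXELS = 5


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI: centre (x, z) in mm from the image centre, on one slice."""

    center_mm: tuple[float, float]
    diameter_mm: float
    slice_index: int


@dataclass(frozen=True)
class RoiStat:
    mean_hu: float
    sigma_hu: float
    n_pixels: int


@dataclass
class UniformityResult:
    slice_index: int
    center: RoiStat
    periphery: dict[str, RoiStat]  # "N", "E", "S", "W"
    max_abs_diff_hu: float
    tolerance_hu: float
    passed: bool


@dataclass
class NoiseResult:
    """Informational only — never graded against baseline or tolerance."""

    slice_index: int
    sigma_small_hu: float
    sigma_big_hu: float
    reference_band_hu: tuple[float, float] = (50.0, 70.0)
    informational: bool = True


@dataclass
class PlugMeasurement:
    hole_index: int
    mean_hu: float
    label: Optional[str] = None
    matched_baseline_hu: Optional[float] = None
    matched_baseline_label: Optional[str] = None
    deviation_hu: Optional[float] = None
    tolerance_hu: Optional[float] = None
    passed: Optional[bool] = None


def roi_mask(volume: Volume, roi: RoiSpec) -> np.ndarray:
    """Boolean 2D membership mask (pixel centre within radius, inclusive)."""
    cx, cz = roi.center_mm
    r = roi.diameter_mm / 2.0
    dx = volume.x_mm() - cx
    dz = volume.z_mm() - cz
    return dx[None, :] ** 2 + dz[:, None] ** 2 <= r**2


def roi_stat(volume: Volume, roi: RoiSpec) -> RoiStat:
    """Mean and sample sigma of the HU values inside an ROI."""
    if not 0 <= roi.slice_index < volume.n_slices:
        raise SliceOutOfRangeError(f"slice {roi.slice_index} outside scan")
    mask = roi_mask(volume, roi)
    values = volume.hu[roi.slice_index][mask].astype(np.float64)
    if values.size < MIN_ROI_PIXELS:
        raise RoiError(
            f"ROI too small: {values.size} pixel(s) at {roi.center_mm} mm, "
            f"diameter {roi.diameter_mm} mm"
        )
    return RoiStat(
        mean_hu=float(values.mean()),
        sigma_hu=float(values.std(ddof=1)),
        n_pixels=int(values.size),
    )


def body_mask(volume: Volume, slice_index: int,
              body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU) -> np.ndarray:
    return volume.hu[slice_index] > body_threshold_hu


def body_center_mm(volume: Volume, slice_index: int,
                   body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU
                   ) -> tuple[float, float]:
    """Centroid (x, z) of the phantom cross-section on one slice."""
    mask = body_mask(volume, slice_index, body_threshold_hu)
    if not mask.any():
        raise RoiError(f"no phantom body on slice {slice_index}")
    rows, cols = np.nonzero(mask)
    return (float(volume.x_mm()[cols].mean()), float(volume.z_mm()[rows].mean()))


def _side_sigma(volume: Volume, middle: int, side: int,
                probe_mm: float = PLUG_SIDE_PROBE_MM) -> float:
    """Mean per-slice in-body sigma over slices on one side of the middle.

    The body mask of the middle slice is reused on every probed slice so
    that air-filled plug holes (which would fall outside a per-slice mask)
    inflate the sigma of the side that holds them.
    """
    t = volume.slice_thickness_mm
    n_probe = max(1, int(round(probe_mm / t)))
    mask = body_mask(volume, middle)
    sigmas = []
    for k in range(1, n_probe + 1):
        idx = middle + side * k
        if not 0 <= idx < volume.n_slices:
            break
        sigmas.append(float(volume.hu[idx][mask].std(ddof=1)))
    if not sigmas:
        return math.inf
    return float(np.mean(sigmas))


def detect_plug_side(volume: Volume, markers: MarkerSet) -> int:
    """+1 if the plug-bearing region lies toward higher slice indices."""
    middle = markers.middle_slice_index
    return +1 if _side_sigma(volume, middle, +1) >= _side_sigma(volume, middle, -1) else -1


def select_uniform_slice(
    volume: Volume,
    markers: MarkerSet,
    offset_mm: float = DEFAULT_UNIFORM_OFFSET_MM,
    direction: Optional[int] = None,
) -> int:
    """The uniformity/noise slice: ``offset_mm`` from the middle slice on the
    side away from the plugs (override with ``direction`` = +-1)."""
    t = volume.slice_thickness_mm
    offset = int(round(offset_mm / t))
    if direction is None:
        direction = -detect_plug_side(volume, markers)
    candidates = [markers.middle_slice_index + direction * offset,
                  markers.middle_slice_index - direction * offset]
    for idx in candidates:
        if 0 <= idx < volume.n_slices:
            return idx
    raise SliceOutOfRangeError(
        f"uniformity slice candidates {candidates} outside scan of "
        f"{volume.n_slices} slices"
    )


def select_contrast_slice(
    volume: Volume,
    markers: MarkerSet,
    offset_mm: float = DEFAULT_CONTRAST_OFFSET_MM,
    direction: Optional[int] = None,
) -> int:
    """The contrast slice: ``offset_mm`` from the middle slice toward the
    plug side (auto-detected as the higher-sigma side)."""
    t = volume.slice_thickness_mm
    if direction is None:
        direction = detect_plug_side(volume, markers)
    idx = markers.middle_slice_index + direction * int(round(offset_mm / t))
    if not 0 <= idx < volume.n_slices:
        raise SliceOutOfRangeError(
            f"contrast slice {idx} outside scan of {volume.n_slices} slices"
        )
    return idx


def uniformity_test(
    volume: Volume,
    markers: MarkerSet,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
    periphery_radius_mm: float = DEFAULT_PERIPHERY_RADIUS_MM,
    tolerance_hu: float = 25.0,
    offset_mm: float = DEFAULT_UNIFORM_OFFSET_MM,
    direction: Optional[int] = None,
    body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
) -> UniformityResult:
    """Centre ROI vs four cardinal periphery ROIs; the largest absolute
    mean difference is graded against ``tolerance_hu`` (inclusive)."""
    idx = select_uniform_slice(volume, markers, offset_mm, direction)
    cx, cz = body_center_mm(volume, idx, body_threshold_hu)
    center_stat = roi_stat(volume, RoiSpec((cx, cz), roi_diameter_mm, idx))
    bmask = body_mask(volume, idx, body_threshold_hu)
    periphery: dict[str, RoiStat] = {}
    offsets = {"N": (0.0, -periphery_radius_mm), "E": (periphery_radius_mm, 0.0),
               "S": (0.0, periphery_radius_mm), "W": (-periphery_radius_mm, 0.0)}
    for name, (ox, oz) in offsets.items():
        roi = RoiSpec((cx + ox, cz + oz), roi_diameter_mm, idx)
        mask = roi_mask(volume, roi)
        if not (mask <= bmask).all():
            raise RoiError(
                f"periphery ROI {name} at ({cx + ox:.1f}, {cz + oz:.1f}) mm "
                "extends outside the phantom"
            )
        periphery[name] = roi_stat(volume, roi)
    max_abs = max(abs(s.mean_hu - center_stat.mean_hu) for s in periphery.values())
    return UniformityResult(
        slice_index=idx,
        center=center_stat,
        periphery=periphery,
        max_abs_diff_hu=max_abs,
        tolerance_hu=tolerance_hu,
        passed=max_abs <= tolerance_hu,
    )


def noise_test(
    volume: Volume,
    markers: MarkerSet,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
    big_roi_diameter_mm: float = DEFAULT_BIG_ROI_DIAMETER_MM,
    offset_mm: float = DEFAULT_UNIFORM_OFFSET_MM,
    direction: Optional[int] = None,
    body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
) -> NoiseResult:
    """sigma_CT of the small and big centre ROIs on the uniform slice."""
    idx = select_uniform_slice(volume, markers, offset_mm, direction)
    cx, cz = body_center_mm(volume, idx, body_threshold_hu)
    small = roi_stat(volume, RoiSpec((cx, cz), roi_diameter_mm, idx))
    big = roi_stat(volume, RoiSpec((cx, cz), big_roi_diameter_mm, idx))
    return NoiseResult(
        slice_index=idx,
        sigma_small_hu=small.sigma_hu,
        sigma_big_hu=big.sigma_hu,
    )


def measure_contrast(
    volume: Volume,
    markers: MarkerSet,
    plug_centers_mm: dict[int, tuple[float, float]],
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
    offset_mm: float = DEFAULT_CONTRAST_OFFSET_MM,
    direction: Optional[int] = None,
    labels: Optional[dict[int, str]] = None,
) -> list[PlugMeasurement]:
    """Mean HU in an ROI at each given hole centre on the contrast slice.

    ``plug_centers_mm`` maps hole index to its (x, z) centre — already
    rotated to the detected phantom orientation.  Ejected (air) holes are
    measured like any other if listed.
    """
    idx = select_contrast_slice(volume, markers, offset_mm, direction)
    labels = labels or {}
    out = []
    for hole, center in sorted(plug_centers_mm.items()):
        stat = roi_stat(volume, RoiSpec(tuple(center), roi_diameter_mm, idx))
        out.append(
            PlugMeasurement(hole_index=hole, mean_hu=stat.mean_hu,
                            label=labels.get(hole))
        )
    return out


def match_to_baseline(
    measured_hus: Sequence[float], baseline_hus: Sequence[float]
) -> list[tuple[int, int]]:
    """One-to-one pairing of measured to baseline HU values minimizing the
    total absolute deviation (plug position is ignored).

    Returns (measured_index, baseline_index) pairs sorted by measured index.
    With unequal lengths the shorter list is fully matched and the surplus
    entries are left unmatched (the caller flags them).
    """
    m = np.asarray(measured_hus, dtype=float)
    b = np.asarray(baseline_hus, dtype=float)
    if m.size == 0 or b.size == 0:
        return []
    cost = np.abs(m[:, None] - b[None, :])
    rows, cols = linear_sum_assignment(cost)
    return sorted(zip(rows.tolist(), cols.tolist()))


def contrast_test(
    measurements: list[PlugMeasurement],
    baseline_hus: Sequence[float],
    baseline_labels: Optional[Sequence[str]] = None,
    tolerances_hu: tuple[float, float] = DEFAULT_CONTRAST_TOLERANCES_HU,
    water_like_limit_hu: float = WATER_LIKE_LIMIT_HU,
    per_plug_tolerance_hu: Optional[dict[str, float]] = None,
) -> list[PlugMeasurement]:
    """Match measured plug HUs to the baseline and grade each deviation.

    Default tolerance: ``tolerances_hu[0]`` (30 HU) when |baseline| is
    within ``water_like_limit_hu``, else ``tolerances_hu[1]`` (50 HU);
    ``per_plug_tolerance_hu`` overrides by baseline label.  Comparisons are
    inclusive.  Unmatched measurements keep ``passed=None``.
    """
    per_plug_tolerance_hu = per_plug_tolerance_hu or {}
    pairs = match_to_baseline(
        [m.mean_hu for m in measurements], list(baseline_hus)
    )
    for mi, bi in pairs:
        meas = measurements[mi]
        base = float(baseline_hus[bi])
        label = baseline_labels[bi] if baseline_labels else None
        tol = per_plug_tolerance_hu.get(
            label,
            tolerances_hu[0] if abs(base) <= water_like_limit_hu else tolerances_hu[1],
        )
        meas.matched_baseline_hu = base
        meas.matched_baseline_label = label
        meas.deviation_hu = meas.mean_hu - base
        meas.tolerance_hu = float(tol)
        meas.passed = abs(meas.deviation_hu) <= tol
    return measurements
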