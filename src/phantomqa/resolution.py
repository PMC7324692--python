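"""Spatial-resolution plug: automatic localization, windowing, manual grade.

The high-contrast resolution plug has an inhomogeneous drilled structure, so
among all plug holes it produces the highest local HU standard deviation.
Candidate slices sit +-35 mm or +-90 mm from the middle slice (the two
possible insertion depths, from either end); the plug is localized as the
global sigma maximum over (candidate slice) x (20 hole positions).  The
assessment itself stays visual: the minimum hole group that must be visible
is 1.6 mm, and the inspector's pass/fail verdict is recorded verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dicom_io import Volume
from .errors import AmbiguousPlugLocationError, SliceOutOfRangeError
from .image_quality import RoiSpec, roi_stat
from .phantom_geometry import MarkerSet

DEFAULT_SEARCH_ROI_DIAMETER_MM = 14.0
DEFAULT_CANDIDATE_OFFSETS_MM = (35.0, -35.0, 90.0, -90.0)
#: Runner-up sigma within this fraction of the best triggers the ambiguity error.
AMBIGUITY_MARGIN = 0.10
DEFAULT_CRITERION_MM = 1.6


@dataclass
class ResolutionResult:
    found_slice_offset_mm: float
    hole_index: int
    plug_sigma_hu: float
    window_bounds_hu: tuple[float, float]
    visual_grade: str = "ungraded"  # "pass" | "fail" | "ungraded"
    criterion_mm: float = DEFAULT_CRITERION_MM
    manual_override: bool = False


def locate_resolution_plug(
    volume: Volume,
    markers: MarkerSet,
    plug_centers_mm: dict[int, tuple[float, float]],
    search_roi_diameter_mm: float = DEFAULT_SEARCH_ROI_DIAMETER_MM,
    candidate_offsets_mm: tuple[float, ...] = DEFAULT_CANDIDATE_OFFSETS_MM,
    override_hole_index: Optional[int] = None,
    override_offset_mm: Optional[float] = None,
) -> tuple[float, int, float]:
    """Locate the resolution plug as the global sigma maximum.

    Returns ``(slice_offset_mm, hole_index, sigma_hu)``.  If the runner-up
    sigma comes within 10% of the maximum the location is ambiguous and an
    :class:`AmbiguousPlugLocationError` is raised — recoverable by passing
    both ``override_hole_index`` and ``override_offset_mm``, which bypass
    the search entirely.
    """
    t = volume.slice_thickness_mm
    middle = markers.middle_slice_index

    if override_hole_index is not None and override_offset_mm is not None:
        idx = middle + int(round(override_offset_mm / t))
        if not 0 <= idx < volume.n_slices:
            raise SliceOutOfRangeError(
                f"override slice offset {override_offset_mm} mm outside scan"
            )
        stat = roi_stat(
            volume,
            RoiSpec(tuple(plug_centers_mm[override_hole_index]),
                    search_roi_diameter_mm, idx),
        )
        return (float(override_offset_mm), int(override_hole_index), stat.sigma_hu)

    scored: list[tuple[float, float, int]] = []  # (sigma, offset, hole)
    for off in candidate_offsets_mm:
        idx = middle + int(round(off / t))
        if not 0 <= idx < volume.n_slices:
            continue
        for hole, center in sorted(plug_centers_mm.items()):
            stat = roi_stat(
                volume, RoiSpec(tuple(center), search_roi_diameter_mm, idx)
            )
            scored.append((stat.sigma_hu, float(off), hole))
    if not scored:
        raise SliceOutOfRangeError(
            "no resolution candidate slice (+-35 / +-90 mm) inside the scan"
        )
    scored.sort(key=lambda s: (-s[0], s[1], s[2]))
    best_sigma, best_off, best_hole = scored[0]
    if len(scored) > 1:
        runner_sigma = scored[1][0]
        if runner_sigma >= (1.0 - AMBIGUITY_MARGIN) * best_sigma:
            raise AmbiguousPlugLocationError(
                "ambiguous plug location: top sigma "
                f"{best_sigma:.1f} HU at (offset {best_off:+.0f} mm, hole "
                f"{best_hole}) vs runner-up {runner_sigma:.1f} HU — supply "
                "the hole index and offset manually"
            )
    return (best_off, best_hole, best_sigma)


def window_plug_image(
    volume: Volume,
    slice_index: int,
    center_mm: tuple[float, float],
    half_width_mm: float = 12.5,
    margin_mm: float = 5.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Crop the plug sub-image and auto-window it.

    Window bounds are the 1st and 99th percentiles of the sub-image HU; a
    constant sub-image gets ``value +- 1`` HU.  A crop extending past the
    image is clipped to the image bounds with a warning.
    """
    import warnings

    if not 0 <= slice_index < volume.n_slices:
        raise SliceOutOfRangeError(f"slice {slice_index} outside scan")
    cx, cz = center_mm
    half = half_width_mm + margin_mm
    x = volume.x_mm()
    z = volume.z_mm()
    cols = np.flatnonzero(np.abs(x - cx) <= half)
    rows = np.flatnonzero(np.abs(z - cz) <= half)
    if cols.size == 0 or rows.size == 0:
        raise SliceOutOfRangeError(f"crop centre {center_mm} mm outside image")
    # Requested extent reaching past the pixel grid is clipped, not an error.
    if (cx - half < x[0] or cx + half > x[-1]
            or cz - half < z[0] or cz + half > z[-1]):
        warnings.warn("plug crop clipped to image bounds", stacklevel=2)
    sub = volume.hu[slice_index, rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    sub = np.asarray(sub, dtype=float)
    lo, hi = float(np.percentile(sub, 1.0)), float(np.percentile(sub, 99.0))
    if lo == hi:
        lo, hi = lo - 1.0, hi + 1.0
    return sub, (lo, hi)


def record_visual_grade(result: ResolutionResult, grade: str) -> ResolutionResult:
    """Record the inspector's verdict ('pass' or 'fail') on a located plug."""
    if grade not in ("pass", "fail"):
        raise ValueError(f"visual grade must be 'pass' or 'fail', got {grade!r}")
    return replace(result, visual_grade=grade)
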