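"""Fiducial marker detection and the geometric-distortion consistency test.

The three high-density fiducial markers embedded in the phantom mid-plane are
found by binarizing the volume at a threshold well above every tissue
substitute (default 800 HU), labelling connected components and taking the
unweighted centroid of each component's pixel centres.  The three transaxial
pairwise distances plus the longitudinal marker-plane-to-surface distance are
then compared against a baseline; the maximum absolute deviation must stay
within 1 mm for SRS/SBRT use (2 mm otherwise), inclusive.

Distance labels: the three edges are reported in ascending length and
labelled A-B <= B-C <= C-A, which makes the labelling invariant under phantom
rotation and marker relabelling; vertex B is the endpoint shared by the two
shortest edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .dicom_io import Volume
from .errors import (
    AmbiguousMarkersError,
    DegenerateMarkersError,
    MarkersNotFoundError,
    SurfaceNotInScanError,
)

DEFAULT_MARKER_THRESHOLD_HU = 800.0
DEFAULT_AREA_LIMITS_PX = (2, 200)
DEFAULT_BODY_THRESHOLD_HU = -300.0
#: Two centroids closer than this are considered the same physical marker.
DEGENERATE_SEPARATION_MM = 1.0


@dataclass
class MarkerSet:
    """Detected fiducial markers.

    ``centroids_mm`` holds exactly three (x, z) points (a fourth detected
    marker is dropped); ``marker_slice_center`` is the sub-slice longitudinal
    position (in slice-index units) of the marker plane, and
    ``middle_slice_index`` its half-up rounding, used to anchor every other
    analysis slice.
    """

    centroids_mm: np.ndarray  # (3, 2) of (x, z)
    middle_slice_index: int
    marker_slice_center: float
    component_areas_px: tuple[int, int, int]


@dataclass
class GeometricResult:
    """Graded geometric-distortion test (distances in mm)."""

    d_ab_mm: float
    d_bc_mm: float
    d_ca_mm: float
    d_bd_mm: float
    baseline_mm: Optional[tuple[float, float, float, float]]
    deviations_mm: Optional[tuple[float, float, float, float]]
    mode: str  # "srs" | "non_srs"
    tolerance_mm: float
    passed: Optional[bool]
    status: str  # "graded" | "baseline_established"

    @property
    def distances_mm(self) -> tuple[float, float, float, float]:
        return (self.d_ab_mm, self.d_bc_mm, self.d_ca_mm, self.d_bd_mm)


def select_best_three(points: np.ndarray) -> tuple[int, int, int]:
    """Of four candidate markers keep the three with maximal pairwise-distance
    sum (tie-break: larger summed component area is handled by the caller;
    final tie-break is scan order, i.e. the lexicographically first triple)."""
    pts = np.asarray(points, dtype=float)
    best = max(
        combinations(range(pts.shape[0]), 3),
        key=lambda ix: (
            sum(
                float(np.linalg.norm(pts[i] - pts[j]))
                for i, j in combinations(ix, 2)
            ),
            # negative index tuple -> prefer earlier scan order on exact ties
            tuple(-i for i in ix),
        ),
    )
    return best


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detect_markers(
    volume: Volume,
    threshold_hu: float = DEFAULT_MARKER_THRESHOLD_HU,
    area_limits_px: tuple[int, int] = DEFAULT_AREA_LIMITS_PX,
) -> MarkerSet:
    """Find the fiducial markers by binarization + connected components.

    A component qualifies when its largest per-slice cross-section area lies
    within ``area_limits_px``.  Exactly three markers are returned: with four
    candidates the triple with maximal pairwise-distance sum is kept (ties
    broken by larger component area, then scan order); fewer than three
    raises :class:`MarkersNotFoundError`, more than four raises
    :class:`AmbiguousMarkersError`.
    """
    binary = volume.hu >= threshold_hu
    slice_hit = binary.any(axis=(1, 2))
    if not slice_hit.any():
        raise MarkersNotFoundError(
            f"no voxels above {threshold_hu} HU — markers not found"
        )
    lo = int(np.argmax(slice_hit))
    hi = len(slice_hit) - 1 - int(np.argmax(slice_hit[::-1]))
    slab = binary[lo : hi + 1]
    labels, n_comp = ndimage.label(slab, structure=np.ones((3, 3, 3), dtype=int))

    x = volume.x_mm()
    z = volume.z_mm()
    candidates = []  # (centroid_xz, slice_center, n_vox, max_area, first_voxel)
    area_min, area_max = area_limits_px
    for comp in range(1, n_comp + 1):
        sl_idx, row_idx, col_idx = np.nonzero(labels == comp)
        per_slice_area = np.bincount(sl_idx)
        max_area = int(per_slice_area.max())
        if not (area_min <= max_area <= area_max):
            continue
        centroid = (float(x[col_idx].mean()), float(z[row_idx].mean()))
        slice_center = float(sl_idx.mean()) + lo
        first_voxel = (int(sl_idx.min()), int(row_idx.min()), int(col_idx.min()))
        candidates.append((centroid, slice_center, sl_idx.size, max_area, first_voxel))

    if len(candidates) < 3:
        raise MarkersNotFoundError(
            f"only {len(candidates)} plausible marker component(s) found "
            f"(threshold {threshold_hu} HU, area {area_limits_px} px) — markers not found"
        )
    if len(candidates) > 4:
        listing = ", ".join(
            f"({c[0][0]:.1f}, {c[0][1]:.1f}) mm / {c[3]} px" for c in candidates
        )
        raise AmbiguousMarkersError(
            f"{len(candidates)} plausible marker components — ambiguous markers: {listing}"
        )

    candidates.sort(key=lambda c: c[4])  # scan order
    pts = np.array([c[0] for c in candidates], dtype=float)
    if len(candidates) == 4:
        best = max(
            combinations(range(4), 3),
            key=lambda ix: (
                sum(
                    float(np.linalg.norm(pts[i] - pts[j]))
                    for i, j in combinations(ix, 2)
                ),
                sum(candidates[i][2] for i in ix),
                tuple(-i for i in ix),
            ),
        )
        candidates = [candidates[i] for i in best]
        pts = pts[list(best)]

    for i, j in combinations(range(3), 2):
        if np.linalg.norm(pts[i] - pts[j]) < DEGENERATE_SEPARATION_MM:
            raise DegenerateMarkersError(
                f"degenerate marker pair: centroids {i} and {j} coincide within "
                f"{DEGENERATE_SEPARATION_MM} mm"
            )

    # The marker plane: unweighted mean slice index over all marker voxels.
    total_vox = sum(c[2] for c in candidates)
    slice_center = sum(c[1] * c[2] for c in candidates) / total_vox
    return MarkerSet(
        centroids_mm=pts,
        middle_slice_index=_round_half_up(slice_center),
        marker_slice_center=slice_center,
        component_areas_px=tuple(c[3] for c in candidates),
    )


def label_edges(centroids_mm: np.ndarray) -> tuple[tuple[float, float, float], int]:
    """Ascending edge lengths (d_ab, d_bc, d_ca) and the index of vertex B
    (the endpoint shared by the two shortest edges)."""
    pts = np.asarray(centroids_mm, dtype=float)
    edges = sorted(
        (float(np.linalg.norm(pts[i] - pts[j])), i, j)
        for i, j in combinations(range(3), 2)
    )
    (d1, i1, j1), (d2, i2, j2), (d3, _, _) = edges
    shared = ({i1, j1} & {i2, j2})
    b_index = shared.pop() if shared else i1
    return (d1, d2, d3), b_index


def transaxial_distances(markers: MarkerSet) -> tuple[float, float, float]:
    """The three pairwise marker distances in mm, ascending (A-B, B-C, C-A)."""
    (d_ab, d_bc, d_ca), _ = label_edges(markers.centroids_mm)
    return (d_ab, d_bc, d_ca)


def longitudinal_distance(
    volume: Volume,
    markers: MarkerSet,
    body_threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU,
) -> float:
    """Marker-plane-to-surface distance (the B-D measurement) in mm.

    The end surface is the outermost slice whose body-mask cross-section
    area reaches 50% of the maximum cross-section; the distance runs from
    the sub-slice marker plane to the outer face of that slice (+0.5 voxel).
    By convention the low-index end is used; if that end is truncated
    (phantom touches the first slice) the other end is used, and if both are
    truncated the surface is not in the scan.
    """
    areas = (volume.hu > body_threshold_hu).sum(axis=(1, 2))
    max_area = int(areas.max())
    if max_area == 0:
        raise SurfaceNotInScanError("no phantom body found in scan")
    in_body = areas >= 0.5 * max_area
    first = int(np.argmax(in_body))
    last = len(in_body) - 1 - int(np.argmax(in_body[::-1]))
    truncated_low = first == 0
    truncated_high = last == len(in_body) - 1
    if truncated_low and truncated_high:
        raise SurfaceNotInScanError(
            "phantom is truncated on both ends — surface not in scan"
        )
    surface = first if not truncated_low else last
    t = volume.slice_thickness_mm
    return (abs(markers.marker_slice_center - surface) + 0.5) * t


def geometric_test(
    measured: Sequence[float],
    baseline: Optional[Sequence[float]],
    mode: str = "srs",
) -> GeometricResult:
    """Grade four measured distances (A-B, B-C, C-A, B-D) against a baseline.

    Tolerance: 1 mm for SRS/SBRT mode, 2 mm otherwise; the comparison is
    inclusive, so a deviation of exactly the tolerance passes.  Without a
    baseline the result is marked "baseline_established" and left ungraded.
    """
    if mode not in ("srs", "non_srs"):
        raise ValueError(f"mode must be 'srs' or 'non_srs', got {mode!r}")
    measured = tuple(float(v) for v in measured)
    if len(measured) != 4:
        raise ValueError("expected 4 measured distances (A-B, B-C, C-A, B-D)")
    if any(v <= 0 for v in measured):
        raise ValueError("distances must be positive")
    tolerance = 1.0 if mode == "srs" else 2.0
    if baseline is None:
        return GeometricResult(
            *measured,
            baseline_mm=None,
            deviations_mm=None,
            mode=mode,
            tolerance_mm=tolerance,
            passed=None,
            status="baseline_established",
        )
    baseline = tuple(float(v) for v in baseline)
    if len(baseline) != 4:
        raise ValueError("incomparable baseline: expected 4 baseline distances")
    deviations = tuple(m - b for m, b in zip(measured, baseline))
    passed = max(abs(d) for d in deviations) <= tolerance
    return GeometricResult(
        *measured,
        baseline_mm=baseline,
        deviations_mm=deviations,
        mode=mode,
        tolerance_mm=tolerance,
        passed=passed,
        status="graded",
    )


def estimate_rotation(
    centroids_mm: np.ndarray, nominal_positions_mm: np.ndarray
) -> float:
    """Estimate the phantom's in-plane rotation (0/90/180/270 degrees) by
    matching detected marker centroids to the nominal marker layout.

    Uses a minimum-cost assignment between the detected points and each
    rotated copy of the nominal layout; returns the rotation with the lowest
    total match distance.
    """
    from . import layout

    detected = np.asarray(centroids_mm, dtype=float)
    nominal = np.atleast_2d(np.asarray(nominal_positions_mm, dtype=float))
    best_deg, best_cost = 0.0, math.inf
    for deg in (0.0, 90.0, 180.0, 270.0):
        rotated = layout.rotate_xy(nominal, deg)
        cost = np.linalg.norm(detected[:, None, :] - rotated[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        total = float(cost[rows, cols].sum())
        if total < best_cost:
            best_deg, best_cost = deg, total
    return best_deg
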