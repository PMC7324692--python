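"""Marker detection, distance measurement and geometric grading."""

from __future__ import annotations

import numpy as np
import pytest

from phantomqa import (
    detect_markers,
    geometric_test,
    longitudinal_distance,
    transaxial_distances,
)
from phantomqa.dicom_io import SeriesMeta, Volume
from phantomqa.errors import (
    AmbiguousMarkersError,
    DegenerateMarkersError,
    MarkersNotFoundError,
    SurfaceNotInScanError,
)
from phantomqa.layout import (
    DEFAULT_MARKER_POSITIONS_MM,
    FOURTH_MARKER_POSITION_MM,
)
from phantomqa.phantom_geometry import MarkerSet, estimate_rotation, label_edges
from phantomqa.synthetic_phantom import PhantomSpec, generate_phantom


def _tiny_volume(blobs, n_slices=3, size=128, spacing=0.76):
    """An air volume with 5x5-pixel marker blobs at given (row, col) centres."""
    hu = np.full((n_slices, size, size), -1024, dtype=np.int16)
    for row, col in blobs:
        hu[1, row - 2 : row + 3, col - 2 : col + 3] = 1100
    meta = SeriesMeta((spacing, spacing), 1.0, n_slices)
    return Volume(hu, meta)


def test_detected_centroids_match_ground_truth(default_phantom, default_markers):
    _, truth = default_phantom
    half_px = 0.5 * 0.76
    detected = default_markers.centroids_mm[
        np.lexsort(default_markers.centroids_mm.T)
    ]
    expected = truth.marker_positions_mm[np.lexsort(truth.marker_positions_mm.T)]
    assert np.abs(detected - expected).max() < half_px
    assert default_markers.middle_slice_index == truth.middle_slice_index


def test_fourth_marker_is_dropped():
    positions = np.vstack([DEFAULT_MARKER_POSITIONS_MM, FOURTH_MARKER_POSITION_MM])
    volume, truth = generate_phantom(
        PhantomSpec(seed=21, marker_positions=positions, slice_thickness_mm=2.0)
    )
    markers = detect_markers(volume)
    assert markers.centroids_mm.shape == (3, 2)
    assert transaxial_distances(markers) == pytest.approx(
        truth.pairwise_distances_mm, abs=0.5 * 0.76
    )


def test_distance_triple_invariant_under_rotation():
    reference = None
    for deg in (0.0, 180.0):
        volume, _ = generate_phantom(
            PhantomSpec(seed=22, rotation_deg=deg, slice_thickness_mm=2.0)
        )
        d = transaxial_distances(detect_markers(volume))
        if reference is None:
            reference = d
        else:
            assert d == pytest.approx(reference, abs=0.5 * 0.76)


def test_edge_labels_ascending_and_vertex_b():
    pts = np.array([[0.0, 0.0], [101.0, 0.0], [196.25, 112.88]])
    (d_ab, d_bc, d_ca), b_idx = label_edges(pts)
    assert d_ab <= d_bc <= d_ca
    assert d_ab == pytest.approx(101.0)
    assert d_ca == pytest.approx(np.linalg.norm(pts[2]))
    # vertex 1 joins the two shortest edges (0-1 and 1-2)
    assert b_idx == 1
    markers = MarkerSet(pts, 0, 0.0, (10, 10, 10))
    assert transaxial_distances(markers) == (d_ab, d_bc, d_ca)


def test_markers_not_found_in_air():
    hu = np.full((3, 64, 64), -1024, dtype=np.int16)
    vol = Volume(hu, SeriesMeta((0.76, 0.76), 1.0, 3))
    with pytest.raises(MarkersNotFoundError, match="not found"):
        detect_markers(vol)


def test_too_many_components_is_ambiguous():
    blobs = [(20, 20), (20, 100), (100, 20), (100, 100), (60, 60)]
    with pytest.raises(AmbiguousMarkersError, match="ambiguous"):
        detect_markers(_tiny_volume(blobs))


def test_coincident_markers_are_degenerate():
    # two disjoint components (slices 0 and 4, nothing between) share the
    # same in-plane centroid -> a degenerate marker pair
    vol = _tiny_volume([(20, 20)], n_slices=5)
    vol.hu[0, 60 - 2 : 60 + 3, 60 - 2 : 60 + 3] = 1100
    vol.hu[4, 60 - 2 : 60 + 3, 60 - 2 : 60 + 3] = 1100
    with pytest.raises(DegenerateMarkersError, match="degenerate"):
        detect_markers(vol)


def test_longitudinal_distance_is_half_length(default_phantom, default_markers):
    volume, truth = default_phantom
    d_bd = longitudinal_distance(volume, default_markers)
    assert d_bd == pytest.approx(90.0, abs=1e-9)
    assert truth.marker_to_surface_mm == 90.0


def test_marker_plane_shift_moves_d_bd_by_same_amount():
    volume, truth = generate_phantom(
        PhantomSpec(seed=23, marker_axial_offset_mm=-5.0)
    )
    markers = detect_markers(volume)
    d_bd = longitudinal_distance(volume, markers)
    assert truth.marker_to_surface_mm == 85.0
    assert d_bd == pytest.approx(85.0, abs=1e-9)


def test_truncated_phantom_has_no_surface():
    # zero scan margin: the phantom fills the whole scan on both ends
    small = PhantomSpec(
        seed=24, diameter_mm=80.0, length_mm=40.0, matrix_size=128,
        marker_positions=DEFAULT_MARKER_POSITIONS_MM * 0.2,
        plug_layout=[], plug_contents={}, scan_margin_mm=0.0,
        slice_thickness_mm=2.0, noise_sigma_hu=0.0,
    )
    volume, _ = generate_phantom(small)
    markers = detect_markers(volume)
    with pytest.raises(SurfaceNotInScanError, match="truncated"):
        longitudinal_distance(volume, markers)


class TestGeometricGrading:
    BASELINE = (101.0, 147.7, 226.4, 89.0)

    def test_reference_machine_deviation_passes(self):
        # 101.3 vs 101.0 mm: 0.3 mm deviation, well inside the 1 mm tolerance
        measured = (101.3, 147.6, 226.6, 89.0)
        res = geometric_test(measured, self.BASELINE, "srs")
        assert res.deviations_mm == pytest.approx((0.3, -0.1, 0.2, 0.0))
        assert res.passed and res.tolerance_mm == 1.0

    def test_identity_always_passes(self):
        res = geometric_test(self.BASELINE, self.BASELINE, "srs")
        assert res.deviations_mm == (0.0, 0.0, 0.0, 0.0)
        assert res.passed

    def test_boundary_deviation_is_inclusive(self):
        # the longitudinal check moving 89.0 -> 90.0 mm sits exactly on the
        # 1 mm SRS/SBRT tolerance and still passes
        measured = (101.0, 147.7, 226.4, 90.0)
        assert geometric_test(measured, self.BASELINE, "srs").passed
        beyond = (101.0, 147.7, 226.4, 90.001)
        assert not geometric_test(beyond, self.BASELINE, "srs").passed

    def test_non_srs_mode_relaxes_to_2mm(self):
        measured = (102.5, 147.7, 226.4, 89.0)
        assert not geometric_test(measured, self.BASELINE, "srs").passed
        assert geometric_test(measured, self.BASELINE, "non_srs").passed

    def test_missing_baseline_establishes_one(self):
        res = geometric_test(self.BASELINE, None, "srs")
        assert res.status == "baseline_established"
        assert res.passed is None and res.deviations_mm is None

    def test_malformed_inputs_rejected(self):
        with pytest.raises(ValueError, match="4"):
            geometric_test((1.0, 2.0, 3.0), self.BASELINE, "srs")
        with pytest.raises(ValueError, match="incomparable|4"):
            geometric_test(self.BASELINE, (1.0, 2.0), "srs")
        with pytest.raises(ValueError, match="mode"):
            geometric_test(self.BASELINE, self.BASELINE, "strict")


def test_rotation_estimated_from_markers():
    from phantomqa.layout import rotate_xy

    for deg in (0.0, 90.0, 180.0, 270.0):
        # small measurement error must not confuse the estimate
        detected = rotate_xy(DEFAULT_MARKER_POSITIONS_MM, deg) + 0.05
        assert estimate_rotation(detected, DEFAULT_MARKER_POSITIONS_MM) == deg
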