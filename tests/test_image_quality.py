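"""ROI statistics, uniformity, noise and contrast analyses.

Two independent oracles live here: a naive per-pixel loop for ROI mean/sigma
and an exhaustive permutation search for the minimum-cost HU matching.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomqa import (
    contrast_test,
    match_to_baseline,
    measure_contrast,
    noise_test,
    roi_stat,
    uniformity_test,
)
from phantomqa.errors import RoiError
from phantomqa.image_quality import (
    PlugMeasurement,
    RoiSpec,
    detect_plug_side,
    select_contrast_slice,
    select_uniform_slice,
)

# Reference machine values: density-plug HU at baseline and after a detector
# replacement (the QA run that flagged the water and bone plugs).
BASELINE_HU = [-685.70, -515.72, -1.12, 97.95, 269.95, 467.28, 668.27]
BASELINE_LABELS = ["LN-300", "LN-450", "Water", "Inner bone", "CB2-30%",
                   "CB2-50%", "Cortical bone"]
DETECTOR_SWAP_HU = [-703.38, -538.26, -41.84, 61.51, 227.09, 409.13, 614.14]


def brute_force_roi(volume, roi: RoiSpec) -> tuple[float, float, int]:
    """Naive per-pixel oracle for ROI mean and sample sigma."""
    cx, cz = roi.center_mm
    r = roi.diameter_mm / 2.0
    x = volume.x_mm()
    z = volume.z_mm()
    values = []
    for i in range(volume.hu.shape[1]):
        for j in range(volume.hu.shape[2]):
            if math.hypot(x[j] - cx, z[i] - cz) <= r:
                values.append(float(volume.hu[roi.slice_index, i, j]))
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), n


def exhaustive_min_cost_pairs(measured, baseline):
    """Exhaustive oracle: the one-to-one pairing minimizing total |diff|."""
    best, best_cost = None, math.inf
    for perm in permutations(range(len(baseline))):
        cost = sum(abs(m - baseline[p]) for m, p in zip(measured, perm))
        if cost < best_cost:
            best, best_cost = perm, cost
    return sorted((i, p) for i, p in enumerate(best)), best_cost


def test_roi_stat_matches_brute_force_loop(default_phantom):
    volume, truth = default_phantom
    gen = np.random.default_rng(77)
    for _ in range(12):  # the acceptance suite covers the full 50-ROI sweep
        roi = RoiSpec(
            center_mm=(float(gen.uniform(-80, 80)), float(gen.uniform(-80, 80))),
            diameter_mm=float(gen.uniform(6, 14)),
            slice_index=int(gen.integers(20, volume.n_slices - 20)),
        )
        stat = roi_stat(volume, roi)
        mean, sigma, n = brute_force_roi(volume, roi)
        assert stat.n_pixels == n
        assert stat.mean_hu == pytest.approx(mean, abs=1e-9)
        assert stat.sigma_hu == pytest.approx(sigma, abs=1e-9)


def test_roi_stat_constant_region_is_exact(noiseless_phantom, noiseless_markers):
    volume, _ = noiseless_phantom
    idx = noiseless_markers.middle_slice_index - 25
    stat = roi_stat(volume, RoiSpec((0.0, 0.0), 10.0, idx))
    assert stat.mean_hu == 0.0 and stat.sigma_hu == 0.0


def test_roi_sigma_estimates_noise(default_phantom, default_markers):
    volume, _ = default_phantom
    idx = default_markers.middle_slice_index - 25
    small = roi_stat(volume, RoiSpec((0.0, 0.0), 10.0, idx))
    assert small.sigma_hu == pytest.approx(20.0, rel=0.15)


def test_tiny_roi_rejected(default_phantom):
    volume, _ = default_phantom
    with pytest.raises(RoiError, match="too small"):
        roi_stat(volume, RoiSpec((0.0, 0.0), 1.0, 50))


def test_uniform_slice_chosen_away_from_plugs(default_phantom, default_markers):
    volume, truth = default_phantom
    assert truth.plug_side == +1
    assert detect_plug_side(volume, default_markers) == +1
    idx = select_uniform_slice(volume, default_markers)
    assert idx == default_markers.middle_slice_index - 10  # 10 mm / 1 mm slices
    contrast_idx = select_contrast_slice(volume, default_markers)
    assert contrast_idx == default_markers.middle_slice_index + 50


def test_uniformity_noiseless_is_exactly_zero(noiseless_phantom, noiseless_markers):
    volume, _ = noiseless_phantom
    res = uniformity_test(volume, noiseless_markers)
    assert res.max_abs_diff_hu == 0.0
    assert res.passed


def test_uniformity_detects_injected_bias(noiseless_phantom, noiseless_markers):
    volume, _ = noiseless_phantom
    biased = volume.copy()
    idx = select_uniform_slice(biased, noiseless_markers)
    # bias a periphery patch (north ROI at 105 mm) by +30 HU
    x = biased.x_mm()
    z = biased.z_mm()
    patch = (x[None, :] ** 2 + (z[:, None] + 105.0) ** 2) <= 10.0**2
    biased.hu[idx][patch] += 30
    res = uniformity_test(biased, noiseless_markers, tolerance_hu=25.0)
    assert res.max_abs_diff_hu == pytest.approx(30.0, abs=1e-9)
    assert not res.passed
    # imaging-only tolerance (30 HU) passes on the inclusive boundary
    assert uniformity_test(biased, noiseless_markers, tolerance_hu=30.0).passed


def test_uniformity_invariant_under_constant_shift(noiseless_phantom,
                                                   noiseless_markers):
    volume, _ = noiseless_phantom
    shifted = volume.copy()
    shifted.hu += 17
    a = uniformity_test(volume, noiseless_markers)
    b = uniformity_test(shifted, noiseless_markers)
    assert a.max_abs_diff_hu == b.max_abs_diff_hu
    assert b.center.mean_hu == a.center.mean_hu + 17.0


def test_sigma_shift_invariant_gain_equivariant(default_phantom, default_markers):
    volume, _ = default_phantom
    idx = default_markers.middle_slice_index - 25
    roi = RoiSpec((0.0, 0.0), 30.0, idx)
    base = roi_stat(volume, roi)
    shifted = volume.copy()
    shifted.hu += 100
    assert roi_stat(shifted, roi).sigma_hu == pytest.approx(base.sigma_hu, abs=1e-12)
    scaled = volume.copy()
    scaled.hu *= 2
    assert roi_stat(scaled, roi).sigma_hu == pytest.approx(2 * base.sigma_hu, rel=1e-12)


def test_noise_sigma_recovered_in_big_roi(default_phantom, default_markers):
    volume, _ = default_phantom
    res = noise_test(volume, default_markers)
    stat_n = math.pi * 30.0**2 / (0.76 * 0.76)
    assert stat_n > 4000  # the big ROI has ample pixels
    assert res.sigma_big_hu == pytest.approx(20.0, rel=0.05)
    assert res.informational


def test_noiseless_noise_is_zero(noiseless_phantom, noiseless_markers):
    volume, _ = noiseless_phantom
    res = noise_test(volume, noiseless_markers)
    assert res.sigma_small_hu == 0.0 and res.sigma_big_hu == 0.0


def test_contrast_recovers_generated_plugs(default_phantom, default_markers):
    volume, truth = default_phantom
    centers = {h: truth.plug_centers_mm[h] for h in truth.plug_hu_map}
    measurements = measure_contrast(volume, default_markers, centers)
    n = math.pi * 5.0**2 / (0.76 * 0.76)
    band = 3 * 20.0 / math.sqrt(n)
    for m in measurements:
        expected = truth.plug_hu_map[m.hole_index]
        if expected <= -1000:  # air floor clips the noise from below
            assert m.mean_hu == pytest.approx(expected, abs=15.0)
        else:
            assert m.mean_hu == pytest.approx(expected, abs=band)


def test_noiseless_plugs_measured_exactly(noiseless_phantom, noiseless_markers):
    volume, truth = noiseless_phantom
    centers = {h: truth.plug_centers_mm[h] for h in truth.plug_hu_map}
    for m in measure_contrast(volume, noiseless_markers, centers):
        assert m.mean_hu == truth.plug_hu_map[m.hole_index]


def test_matching_identity_and_permutation_invariance():
    pairs = match_to_baseline(BASELINE_HU, BASELINE_HU)
    assert pairs == [(i, i) for i in range(7)]
    perm = [3, 0, 6, 1, 5, 2, 4]
    permuted = [BASELINE_HU[p] for p in perm]
    pairs = match_to_baseline(permuted, BASELINE_HU)
    assert [(i, p) for i, p in enumerate(perm)] == pairs


def test_detector_swap_values_match_by_material():
    """The post-detector-swap HUs pair with their own material's baseline
    under minimum total |deviation| — verified against exhaustive search."""
    pairs = match_to_baseline(DETECTOR_SWAP_HU, BASELINE_HU)
    oracle_pairs, oracle_cost = exhaustive_min_cost_pairs(
        DETECTOR_SWAP_HU, BASELINE_HU
    )
    assert pairs == oracle_pairs
    assert pairs == [(i, i) for i in range(7)]  # identity by material
    got_cost = sum(abs(m - BASELINE_HU[b]) for (m, (_, b))
                   in zip(DETECTOR_SWAP_HU, pairs))
    assert got_cost == pytest.approx(oracle_cost, abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.integers(min_value=2, max_value=6).flatmap(
        lambda n: st.tuples(
            st.lists(st.floats(-800, 800), min_size=n, max_size=n),
            st.lists(st.floats(-800, 800), min_size=n, max_size=n),
        )
    )
)
def test_matching_is_optimal_on_arbitrary_lists(lists):
    """No one-to-one pairing beats the assignment's total |deviation|."""
    measured, baseline = lists
    pairs = match_to_baseline(measured, baseline)
    _, oracle_cost = exhaustive_min_cost_pairs(measured, baseline)
    cost = sum(abs(measured[i] - baseline[j]) for i, j in pairs)
    assert cost == pytest.approx(oracle_cost, abs=1e-9)


def test_length_mismatch_leaves_surplus_unmatched():
    meas = [PlugMeasurement(hole_index=i, mean_hu=v)
            for i, v in enumerate([-700.0, 0.0, 500.0])]
    graded = contrast_test(meas, [-690.0, 2.0])
    assert sum(m.passed is not None for m in graded) == 2
    assert [m.passed is None for m in graded] == [False, False, True]


def test_contrast_grading_thresholds():
    meas = [PlugMeasurement(hole_index=i, mean_hu=v)
            for i, v in enumerate(DETECTOR_SWAP_HU)]
    graded = contrast_test(meas, BASELINE_HU, BASELINE_LABELS)
    by_label = {m.matched_baseline_label: m for m in graded}
    # water drifted by 40.72 HU: outside the 30 HU water-like tolerance
    water = by_label["Water"]
    assert water.deviation_hu == pytest.approx(-40.72)
    assert water.tolerance_hu == 30.0 and not water.passed
    # LN-300 drifted 17.68 HU: inside the 50 HU tolerance for dense plugs
    ln300 = by_label["LN-300"]
    assert ln300.deviation_hu == pytest.approx(-17.68)
    assert ln300.tolerance_hu == 50.0 and ln300.passed
    # zero deviation always passes
    same = contrast_test(
        [PlugMeasurement(hole_index=0, mean_hu=-1.12)], [-1.12], ["Water"]
    )[0]
    assert same.deviation_hu == 0.0 and same.passed


def test_per_plug_tolerance_override():
    meas = [PlugMeasurement(hole_index=0, mean_hu=-41.84)]
    graded = contrast_test(
        meas, [-1.12], ["Water"], per_plug_tolerance_hu={"Water": 45.0}
    )
    assert graded[0].tolerance_hu == 45.0 and graded[0].passed
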