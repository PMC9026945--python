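import numpy as np
import pytest
from scipy import ndimage as ndi

from hspseg import (
    ContractError,
    Mask3D,
    RegionGrowParams,
    SeedPoint,
    Volume3D,
    compute_volume,
    correct_seed,
    grow_plaque_region,
    initial_threshold,
    muscle_mean,
    segment,
    segment_hsp,
    smooth_volume,
)
from oracles import window_argmax, window_max


# ---------------------------------------------------------------- seed window


def test_correct_seed_tie_breaks_lexicographically():
    vol = Volume3D(np.full((9, 9, 9), 5.0))
    out = correct_seed(vol, SeedPoint(4, 4, 4), window_radius=3)
    assert out.as_tuple() == (1, 1, 1)  # lowest corner of the clipped window
    assert out.kind == "corrected"


def test_correct_seed_finds_unique_maximum():
    data = np.zeros((11, 11, 11))
    data[5, 5, 5] = 200.0
    out = correct_seed(Volume3D(data), SeedPoint(4, 4, 4), window_radius=3)
    assert out.as_tuple() == (5, 5, 5)


def test_correct_seed_matches_exhaustive_window_scan(small_volume, rng):
    for _ in range(100):
        center = tuple(int(c) for c in rng.integers(0, 15, size=3))
        got = correct_seed(small_volume, SeedPoint(*center), window_radius=3)
        assert got.as_tuple() == window_argmax(small_volume.data, center, 3)


def test_correct_seed_out_of_bounds_is_contract_error(small_volume):
    with pytest.raises(ContractError):
        correct_seed(small_volume, SeedPoint(0, 0, 15))


# ------------------------------------------------------------------ smoothing


def test_smooth_sigma_zero_is_identity(small_volume):
    out = smooth_volume(small_volume, 0.0)
    np.testing.assert_array_equal(out.data, small_volume.data)
    assert out.spacing == small_volume.spacing


def test_smooth_preserves_constant_volumes():
    vol = Volume3D(np.full((10, 10, 10), 42.0))
    out = smooth_volume(vol, 0.5)
    np.testing.assert_allclose(out.data, 42.0, atol=1e-9)


def test_smooth_impulse_center_equals_kernel_central_weight():
    """The response to a unit impulse is the discrete Gaussian kernel itself."""
    sigma = 0.5
    radius = int(4.0 * sigma + 0.5)  # same truncation rule as the implementation
    x = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    w /= w.sum()
    central_3d = w[radius] ** 3

    data = np.zeros((21, 21, 21))
    data[10, 10, 10] = 1.0
    out = smooth_volume(Volume3D(data), sigma)
    assert out.data[10, 10, 10] == pytest.approx(central_3d, rel=1e-9)


def test_smooth_negative_sigma_is_contract_error(small_volume):
    with pytest.raises(ContractError):
        smooth_volume(small_volume, -0.1)


# ---------------------------------------------------------- initial threshold


def test_initial_threshold_constant_and_seed_max():
    const = Volume3D(np.full((9, 9, 9), 7.0))
    assert initial_threshold(const, SeedPoint(4, 4, 4, kind="corrected")) == 7.0
    data = np.zeros((9, 9, 9))
    data[4, 4, 4] = 200.0
    assert initial_threshold(Volume3D(data), SeedPoint(4, 4, 4, kind="corrected")) == 200.0


def test_initial_threshold_matches_window_scan(small_volume, rng):
    for _ in range(50):
        center = tuple(int(c) for c in rng.integers(0, 15, size=3))
        seed = SeedPoint(*center, kind="corrected")
        assert initial_threshold(small_volume, seed, 3) == window_max(
            small_volume.data, center, 3
        )


# ---------------------------------------------------------------- muscle mean


def test_muscle_mean_hand_values():
    data = np.full((6, 6, 6), 120.0)
    roi = np.zeros((6, 6, 6), dtype=bool)
    roi[1:3, 1:3, 1:3] = True
    assert muscle_mean(Volume3D(data), Mask3D(roi)) == 120.0

    data[0, 0, 0], data[0, 0, 1] = 100.0, 140.0
    two = np.zeros_like(roi)
    two[0, 0, :2] = True
    assert muscle_mean(Volume3D(data), Mask3D(two)) == 120.0


def test_muscle_mean_matches_direct_summation(small_volume, rng):
    roi = rng.random(small_volume.shape) < 0.2
    expected = small_volume.data[roi].sum() / roi.sum()
    assert muscle_mean(small_volume, Mask3D(roi)) == pytest.approx(expected, rel=1e-12)


def test_muscle_mean_empty_roi_is_contract_error(small_volume):
    with pytest.raises(ContractError):
        muscle_mean(small_volume, Mask3D(np.zeros(small_volume.shape, dtype=bool)))


# ------------------------------------------------------------ HSP thresholding


def test_segment_hsp_elementwise_oracle(small_volume, rng):
    plaque = Mask3D(rng.random(small_volume.shape) < 0.3)
    hsp, thr = segment_hsp(small_volume, plaque, muscle_mean_value=90.0, coefficient=1.3)
    expected = plaque.data & (small_volume.data > 90.0 * 1.3)
    np.testing.assert_array_equal(hsp.data, expected)
    assert thr == pytest.approx(117.0)
    assert not np.any(hsp.data & ~plaque.data)  # HSP is inside the plaque


def test_segment_hsp_empty_when_threshold_above_plaque_max(small_volume):
    plaque = Mask3D(np.ones(small_volume.shape, dtype=bool))
    hsp, _ = segment_hsp(small_volume, plaque, muscle_mean_value=1e6, coefficient=1.3)
    assert hsp.count() == 0


def test_segment_hsp_monotone_in_coefficient(small_volume, rng):
    """Lowering the contrast-ratio coefficient never shrinks the HSP mask."""
    plaque = Mask3D(rng.random(small_volume.shape) < 0.5)
    previous = None
    for coeff in (1.52, 1.3, 1.1, 0.9):
        hsp, _ = segment_hsp(small_volume, plaque, 100.0, coefficient=coeff)
        if previous is not None:
            assert np.all(previous.data <= hsp.data)
        previous = hsp


# ------------------------------------------------------------------- volumes


def test_compute_volume_single_voxel_and_empty():
    mask = np.zeros((5, 5, 5), dtype=bool)
    assert compute_volume(Mask3D(mask, spacing=(0.45, 0.45, 0.9))) == 0.0
    mask[2, 2, 2] = True
    vol = compute_volume(Mask3D(mask, spacing=(0.45, 0.45, 0.9)))
    assert vol == pytest.approx(0.18225, rel=1e-12)


def test_compute_volume_methods_agree_on_random_masks(rng):
    for _ in range(20):
        mask = Mask3D(rng.random((9, 10, 11)) < 0.4, spacing=(0.45, 0.45, 0.9))
        a = compute_volume(mask, method="voxel_sum")
        b = compute_volume(mask, method="slice_area")
        assert b == pytest.approx(a, rel=1e-9)


# ------------------------------------------------------------- region growing


def _cuboid_scene():
    data = np.full((20, 20, 20), 100.0)
    data[6:11, 6:11, 6:11] = 300.0
    return data


def test_grow_recovers_bright_cuboid_exactly():
    data = _cuboid_scene()
    vol = Volume3D(data)
    seed = correct_seed(vol, SeedPoint(8, 8, 8), 3)
    params = RegionGrowParams(sigma=0.0)
    mask, trace = grow_plaque_region(vol, seed, params)
    expected = data == 300.0
    np.testing.assert_array_equal(mask.data, expected)
    assert trace.initial_threshold == 300.0


def test_grow_degenerate_seed_returns_one_voxel():
    data = np.full((9, 9, 9), 5.0)
    data[4, 4, 4] = 10.0
    mask, trace = grow_plaque_region(Volume3D(data), SeedPoint(4, 4, 4, kind="corrected"))
    assert mask.count() == 1
    assert mask.data[4, 4, 4]
    assert trace.stop_reason == "no_new_voxels"


def test_grow_trace_is_nested_and_strictly_decreasing(phantom_noise_free):
    ph = phantom_noise_free
    smoothed = smooth_volume(ph.volume, 0.5)
    seed = correct_seed(smoothed, ph.manual_seed, 3)
    _, trace = grow_plaque_region(smoothed, seed)
    thresholds = [s.threshold for s in trace.steps]
    cumulative = [s.cumulative for s in trace.steps]
    assert all(b - a == pytest.approx(-1.0) for a, b in zip(thresholds, thresholds[1:]))
    assert all(b >= a for a, b in zip(cumulative, cumulative[1:]))
    assert trace.stop_reason in {"no_new_voxels", "volume_doubled", "floor_reached"}


def test_grow_mask_is_single_component_containing_seed(phantom_noise_free):
    ph = phantom_noise_free
    for conn, rank in ((6, 1), (26, 3)):
        smoothed = smooth_volume(ph.volume, 0.5)
        seed = correct_seed(smoothed, ph.manual_seed, 3)
        mask, _ = grow_plaque_region(
            smoothed, seed, RegionGrowParams(connectivity=conn)
        )
        labels, n = ndi.label(mask.data, structure=ndi.generate_binary_structure(3, rank))
        assert n == 1
        assert mask.data[seed.as_tuple()]


# ----------------------------------------------------------------- end-to-end


def test_segment_is_deterministic(phantom_noise_free):
    ph = phantom_noise_free
    first = segment(ph.volume, ph.manual_seed, ph.muscle_roi)
    second = segment(ph.volume, ph.manual_seed, ph.muscle_roi)
    np.testing.assert_array_equal(first.plaque_mask.data, second.plaque_mask.data)
    np.testing.assert_array_equal(first.hsp_mask.data, second.hsp_mask.data)
    assert first.summary() == second.summary()


def test_segment_result_invariants(phantom_noise_free):
    ph = phantom_noise_free
    res = segment(ph.volume, ph.manual_seed, ph.muscle_roi)
    assert not np.any(res.hsp_mask.data & ~res.plaque_mask.data)
    assert np.all(ph.volume.data[res.hsp_mask.data] > res.hsp_threshold)
    assert res.hsp_threshold == pytest.approx(res.muscle_mean * res.coefficient)
    assert 0 <= res.hsp_volume_mm3 <= res.plaque_volume_mm3


def test_segment_yields_empty_hsp_when_muscle_is_brighter(phantom_noise_free):
    ph = phantom_noise_free
    bright = Volume3D(ph.volume.data.copy(), spacing=ph.volume.spacing)
    bright.data[ph.muscle_roi.data] = 1e5  # muscle mean far above any plaque voxel
    res = segment(bright, ph.manual_seed, ph.muscle_roi)
    assert res.hsp_volume_mm3 == 0.0
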