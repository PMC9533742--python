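"""Synthetic frame rendering, sampling and intensity pre-processing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scattergap.geometry import GapMask
from scattergap.synthetic import (
    Peak,
    Ring,
    ScatterScene,
    SceneRanges,
    apply_mask,
    preprocess,
    render_scene,
    resize_bicubic,
    sample_scene,
    simulate_pair,
)


class TestRenderScene:
    def test_empty_scene_is_all_zero(self):
        frame = render_scene(ScatterScene(center=(16, 16)), 32, 32)
        assert frame.shape == (32, 32)
        assert np.all(frame == 0)

    def test_single_ring_peaks_at_its_radius(self):
        scene = ScatterScene(center=(64, 64), rings=(Ring(30, 3, 1.0),))
        frame = render_scene(scene, 128, 128)
        rows = np.arange(128)[:, None] - 64.0
        cols = np.arange(128)[None, :] - 64.0
        r = np.hypot(rows, cols)
        best = np.unravel_index(frame.argmax(), frame.shape)
        assert abs(r[best] - 30) <= np.abs(r - 30).min() + 0.5

    def test_same_seed_renders_identically(self):
        scene = ScatterScene(center=(10, 10), noise_sigma=1.0, seed=42,
                             background_amplitude=5.0)
        a = render_scene(scene, 24, 24)
        b = render_scene(scene, 24, 24)
        assert np.array_equal(a, b)

    def test_beamstop_region_is_zero(self):
        scene = ScatterScene(center=(16, 16), background_amplitude=10.0,
                             beamstop_halfwidth=3.0)
        frame = render_scene(scene, 32, 32)
        assert np.all(frame[14:19, 14:19] == 0)
        assert frame[0, 0] > 0

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            render_scene(ScatterScene(center=(1, 1)), 0, 5)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ScatterScene(center=(1, 1), rings=(Ring(5, 1, -1.0),))


class TestSampleScene:
    def test_degenerate_ranges_give_determined_values(self, rng):
        ranges = SceneRanges(
            center_jitter=0.0, n_rings=(1, 1), ring_radius=(0.2, 0.2),
            ring_width=(2.0, 2.0), ring_amplitude=(1.0, 1.0), p_modulated=0.0,
            n_peaks=(0, 0), background_amplitude=(3.0, 3.0),
            background_decay=(1.0, 1.0), beamstop_halfwidth=(5.0, 5.0),
            noise_sigma=(0.0, 0.0), p_gap_peak=0.0, p_beamstop_peaks=0.0,
            p_fourfold=0.0,
        )
        scene = sample_scene(rng, ranges, 100, 100)
        assert scene.center == (50.0, 50.0)
        assert len(scene.rings) == 1 and scene.rings[0].radius == pytest.approx(20.0)
        assert scene.background_amplitude == 3.0

    def test_fixed_seed_reproduces_scene(self):
        a = sample_scene(np.random.default_rng(5))
        b = sample_scene(np.random.default_rng(5))
        assert a == b

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty range"):
            SceneRanges(ring_width=(3.0, 2.0))

    def test_fourfold_frequency_within_binomial_bound(self):
        rng = np.random.default_rng(77)
        ranges = SceneRanges(p_fourfold=0.2, n_peaks=(0, 0), p_gap_peak=0.0,
                             p_beamstop_peaks=0.0)
        n = 1000
        count = sum(
            len(sample_scene(rng, ranges).peaks) == 4 for _ in range(n)
        )
        sigma = np.sqrt(n * 0.2 * 0.8)
        assert abs(count - n * 0.2) < 3 * sigma

    def test_gap_peak_lands_inside_a_horizontal_band(self, mask512):
        rng = np.random.default_rng(3)
        ranges = SceneRanges(p_gap_peak=1.0, n_peaks=(0, 0), p_beamstop_peaks=0.0,
                             p_fourfold=0.0)
        scene = sample_scene(rng, ranges, 512, 512, gap_mask=mask512)
        pk = scene.peaks[-1]
        assert any(r0 <= pk.row < r1 for r0, r1, _, _ in mask512.horizontal_rectangles)


class TestResizeBicubic:
    def test_constant_frame_stays_constant(self):
        out = resize_bicubic(np.full((64, 48), 3.5), 32, 24)
        assert out.shape == (32, 24)
        np.testing.assert_allclose(out, 3.5, rtol=1e-12)

    def test_linear_ramp_reproduced_at_interior_points(self):
        r, c = np.mgrid[0:128, 0:128]
        ramp = 1.0 + 0.01 * r + 0.02 * c
        out = resize_bicubic(ramp, 64, 64)
        # cubic interpolation reproduces degree-1 polynomials away from edges
        rr = (np.arange(64) + 0.5) * 2 - 0.5
        cc = rr
        expected = 1.0 + 0.01 * rr[:, None] + 0.02 * cc[None, :]
        np.testing.assert_allclose(out[4:-4, 4:-4], expected[4:-4, 4:-4], rtol=1e-6)

    def test_negative_overshoot_clipped(self):
        frame = np.zeros((16, 16))
        frame[8, 8] = 100.0
        out = resize_bicubic(frame, 32, 32)
        assert out.min() >= 0.0

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            resize_bicubic(np.ones((3, 10)), 8, 8)


class TestPreprocess:
    def test_constant_frame_maps_to_zero(self):
        assert np.all(preprocess(np.full((4, 4), 7.0)) == 0)

    def test_two_value_frame_hits_unit_interval_ends(self):
        out = preprocess(np.array([[0.0, np.e - 1.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_rejects_nan_and_negative(self):
        with pytest.raises(ValueError):
            preprocess(np.array([[1.0, np.nan]]))
        with pytest.raises(ValueError):
            preprocess(np.array([[-1.0, 2.0]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_range_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.gamma(1.5, 100.0, size=(12, 12))
        out = preprocess(frame)
        assert out.min() >= 0.0 and out.max() <= 1.0
        order = np.argsort(frame.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= 0)


class TestApplyMask:
    def test_empty_mask_returns_input(self):
        frame = np.arange(16.0).reshape(4, 4)
        out = apply_mask(frame, GapMask(np.zeros((4, 4), bool)))
        assert np.array_equal(out, frame)

    def test_full_mask_gives_fill(self):
        raster = np.ones((3, 3), bool)
        mask = GapMask(raster, ((0, 3, 0, 3),))
        assert np.all(apply_mask(np.random.rand(3, 3), mask, fill=0.5) == 0.5)

    def test_idempotent(self, mask512):
        frame = np.random.default_rng(0).random((512, 512))
        once = apply_mask(frame, mask512)
        assert np.array_equal(apply_mask(once, mask512), once)

    def test_shape_mismatch_rejected(self, mask512):
        with pytest.raises(ValueError):
            apply_mask(np.zeros((10, 10)), mask512)


class TestSimulatePair:
    def test_truth_fills_horizontal_gaps_but_not_vertical(self, mask512, rng):
        scene = sample_scene(rng, SceneRanges(), 512, 512, gap_mask=mask512)
        masked, truth = simulate_pair(scene, mask512)
        h = mask512.horizontal_only().raster & ~mask512.vertical_only().raster
        v = mask512.vertical_only().raster
        assert np.all(masked[mask512.raster] == 0)
        assert truth[h].max() > 0
        assert np.all(truth[v] == 0)
        outside = ~mask512.raster
        assert np.array_equal(masked[outside], truth[outside])

    def test_keep_vertical_flag_fills_everything(self, mask512, rng):
        scene = sample_scene(rng, SceneRanges(), 512, 512, gap_mask=mask512)
        _, truth = simulate_pair(scene, mask512, keep_vertical_in_truth=True)
        assert truth[mask512.vertical_only().raster].max() > 0
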