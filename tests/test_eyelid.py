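import numpy as np
import pytest
from oracles import ransac_consensus

import blinkscope as bs
from blinkscope.eyelid import (
    EyelidCurve,
    Roi,
    accumulate_dynamic_image,
    binarization_threshold,
    estimate_clip,
    find_roi,
    interpolate_eyelid,
    raw_upper_edge,
    remove_outliers,
)
from blinkscope.video_io import FrameSequence


def _curve(y):
    y = np.asarray(y, dtype=float)
    return EyelidCurve(y=y, inlier_mask=~np.isnan(y))


class TestBinarizationThreshold:
    def test_bimodal_valley_separates_classes(self):
        img = np.concatenate([np.full(500, 60), np.full(500, 200)]).reshape(25, 40)
        thr = binarization_threshold(img.astype(np.uint8))
        assert 60 < thr < 200
        assert ((img < thr) == (img == 60)).all()

    def test_constant_image_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            binarization_threshold(np.full((10, 10), 77, dtype=np.uint8))

    def test_separates_eye_pixels_on_clean_render(self, noise_free_blink):
        seq, _ = noise_free_blink
        scene = bs.SceneSpec(noise_sd=0.0)
        thr = binarization_threshold(seq.frames[0])
        assert scene.eye_gray < thr < scene.skin_gray
        binary = seq.frames[0] < thr
        truth = seq.frames[0] == scene.eye_gray
        np.testing.assert_array_equal(binary, truth)


class TestDynamicImage:
    def test_static_clip_accumulates_zero(self):
        clip = FrameSequence(frames=np.full((5, 8, 8), 200, dtype=np.uint8), fps=240)
        assert (accumulate_dynamic_image(clip, 128) == 0).all()

    def test_toggling_pixel_counts_transitions(self):
        frames = np.full((6, 4, 4), 200, dtype=np.uint8)
        frames[1::2, 2, 2] = 10  # below threshold on odd frames
        clip = FrameSequence(frames=frames, fps=240)
        acc = accumulate_dynamic_image(clip, 100)
        assert acc[2, 2] == 5  # N - 1 transitions
        acc[2, 2] = 0
        assert (acc == 0).all()

    def test_blob_overlaps_eyelid_sweep(self, noise_free_blink):
        seq, gt = noise_free_blink
        thr = binarization_threshold(seq.frames[0])
        acc = accumulate_dynamic_image(seq, thr)
        roi = find_roi(acc, margin=0)
        # the swept band spans the apex's full vertical travel
        top, bottom = gt.eyelid_y.min(), gt.eyelid_y.max()
        assert roi.top <= top + 2
        assert roi.top + roi.height >= bottom - 2


class TestFindRoi:
    def test_single_blob_bbox(self):
        acc = np.zeros((60, 80), dtype=int)
        acc[20:30, 30:40] = 7
        roi = find_roi(acc, margin=0)
        assert (roi.top, roi.left, roi.height, roi.width) == (20, 30, 10, 10)

    def test_heavier_blob_wins(self):
        acc = np.zeros((50, 50), dtype=float)
        acc[5:10, 5:10] = 20    # sum 500
        acc[30:40, 30:40] = 9   # sum 900
        roi = find_roi(acc, margin=0)
        assert (roi.top, roi.left) == (30, 30)

    def test_margin_clamped_to_bounds(self):
        acc = np.zeros((20, 20))
        acc[0:4, 0:4] = 5
        roi = find_roi(acc, margin=10)
        assert (roi.top, roi.left) == (0, 0)
        assert roi.height <= 20 and roi.width <= 20

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no motion"):
            find_roi(np.zeros((10, 10)))

    def test_translation_equivariance(self, rng):
        acc = np.zeros((64, 64))
        acc[10:20, 12:22] = rng.uniform(1, 5, (10, 10))
        r0 = find_roi(acc, margin=2)
        shifted = np.roll(np.roll(acc, 7, axis=0), 11, axis=1)
        r1 = find_roi(shifted, margin=2)
        assert (r1.top - r0.top, r1.left - r0.left) == (7, 11)


class TestRawUpperEdge:
    def test_all_white_all_missing(self):
        curve = raw_upper_edge(np.zeros((10, 12), dtype=bool))
        assert np.isnan(curve.y).all()

    def test_filled_rectangle_top_row(self):
        binary = np.zeros((30, 8), dtype=bool)
        binary[10:21] = True
        curve = raw_upper_edge(binary)
        assert (curve.y == 10).all()

    def test_mixed_columns(self):
        binary = np.zeros((10, 3), dtype=bool)
        binary[4:, 0] = True
        binary[7:, 2] = True
        curve = raw_upper_edge(binary)
        assert curve.y[0] == 4 and np.isnan(curve.y[1]) and curve.y[2] == 7


class TestRemoveOutliers:
    def test_single_displaced_point_identified_and_coeffs_recovered(self):
        y = 0.01 * np.arange(50) ** 2 + 30.0
        y[20] += 40
        out = remove_outliers(_curve(y))
        assert list(np.flatnonzero(~out.inlier_mask)) == [20]
        np.testing.assert_allclose(out.poly_coeffs, [0.01, 0.0, 30.0], atol=1e-6)

    def test_consistent_line_keeps_everything(self):
        y = 2.0 * np.arange(20) + 5.0
        out = remove_outliers(_curve(y), degree=2)
        assert out.inlier_mask.all()
        resid = y - np.polyval(out.poly_coeffs, np.arange(20))
        np.testing.assert_allclose(resid, 0, atol=1e-9)

    def test_heavily_contaminated_parabola(self):
        """6 points on a parabola + 4 gross outliers -> exactly the 6 survive."""
        y = 0.05 * np.arange(10) ** 2 + 10.0
        y[[1, 4, 6, 8]] += np.array([55, -60, 70, 45])
        out = remove_outliers(_curve(y))
        assert list(np.flatnonzero(out.inlier_mask)) == [0, 2, 3, 5, 7, 9]

    def test_matches_exhaustive_ransac_consensus(self, rng):
        """Iterative trimming agrees with sampling RANSAC on random instances."""
        agree = 0
        n_instances = 100
        for _ in range(n_instances):
            n = int(rng.integers(10, 16))
            coeffs = [rng.uniform(-0.1, 0.1), rng.uniform(-2, 2), rng.uniform(10, 60)]
            y = np.polyval(coeffs, np.arange(n)) + rng.uniform(-0.5, 0.5, n)
            k = int(rng.integers(0, 5))
            idx = rng.choice(n, size=k, replace=False)
            y[idx] += rng.choice([-1, 1], k) * rng.uniform(31, 120, k)
            got = remove_outliers(_curve(y)).inlier_mask
            agree += np.array_equal(got, ransac_consensus(y))
        assert agree >= 0.98 * n_instances

    def test_never_grows_and_idempotent(self, rng):
        y = np.polyval([0.02, -1, 40], np.arange(30)) + rng.normal(0, 1, 30)
        y[[3, 17]] += [50, -45]
        out = remove_outliers(_curve(y))
        assert out.inlier_mask.sum() <= 30
        again = remove_outliers(out)
        np.testing.assert_array_equal(again.inlier_mask, out.inlier_mask)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            remove_outliers(_curve([1.0, 2.0, np.nan, np.nan, np.nan]))


class TestInterpolate:
    def test_gap_filled_from_parabola(self):
        y = 0.02 * np.arange(40) ** 2 + 12.0
        y[15:20] = np.nan
        fitted = remove_outliers(_curve(y))
        full = interpolate_eyelid(fitted)
        analytic = 0.02 * np.arange(15, 20) ** 2 + 12.0
        np.testing.assert_allclose(full.y[15:20], analytic, atol=0.5)
        assert not np.isnan(full.y).any()

    def test_no_gaps_is_identity(self):
        y = np.linspace(5, 25, 30)
        fitted = remove_outliers(_curve(y))
        full = interpolate_eyelid(fitted)
        np.testing.assert_allclose(full.y, y, atol=1e-9)

    def test_edge_gaps_stay_missing(self):
        y = 0.01 * np.arange(30) ** 2 + 8.0
        y[:4] = np.nan
        y[-3:] = np.nan
        full = interpolate_eyelid(remove_outliers(_curve(y)))
        assert np.isnan(full.y[:4]).all() and np.isnan(full.y[-3:]).all()
        assert not np.isnan(full.y[4:-3]).any()


def test_end_to_end_recovery_noise_free(noise_free_blink):
    """Estimated eyelid center within 1 px of truth on >= 95% of frames."""
    seq, gt = noise_free_blink
    scene = bs.SceneSpec(noise_sd=0.0)
    est = estimate_clip(seq)
    errors = []
    for i, curve in enumerate(est.curves):
        center_col = scene.width / 2 - est.roi.left
        center_row = np.polyval(curve.poly_coeffs, center_col) + est.roi.top
        errors.append(abs(center_row - gt.eyelid_y[i]))
    assert np.mean(np.asarray(errors) <= 1.0) >= 0.95


def test_end_to_end_recovery_noisy():
    """At sensor noise sd 5, center stays within 2 px on >= 90% of frames."""
    scene = bs.SceneSpec(noise_sd=5.0, seed=21)
    seq, gt = bs.render_blink_video(
        [bs.BlinkSpec(pre_open_ms=100, close_ms=116, closed_ms=30, open_ms=216,
                      post_open_ms=100, amplitude=1.0)],
        scene, fps=240.0,
    )
    est = estimate_clip(seq)
    errors = []
    for i, curve in enumerate(est.curves):
        center_col = scene.width / 2 - est.roi.left
        center_row = np.polyval(curve.poly_coeffs, center_col) + est.roi.top
        errors.append(abs(center_row - gt.eyelid_y[i]))
    assert np.mean(np.asarray(errors) <= 2.0) >= 0.90
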