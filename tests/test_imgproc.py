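"""Image preparation and thresholding: hand-checkable values and invariants."""

import numpy as np
import pytest
from scipy import ndimage

import tracequant as tq


def rect_roi(x0, y0, x1, y1, purpose="background"):
    return tq.RoiSpec("r", "ipsi", ((x0, y0), (x1, y0), (x1, y1), (x0, y1)), purpose)


class TestGrayscale:
    def test_single_channel_is_identity(self):
        m = tq.Micrograph(np.arange(12, dtype=float).reshape(3, 4))
        assert tq.to_grayscale(m) is m

    def test_three_channel_unweighted_mean(self):
        rgb = np.zeros((2, 2, 3))
        rgb[0, 0] = (30, 60, 90)
        out = tq.to_grayscale(tq.Micrograph(rgb))
        assert out.raster[0, 0] == 60.0
        assert out.raster.shape == (2, 2)

    def test_all_zero_image_stays_zero(self):
        out = tq.to_grayscale(tq.Micrograph(np.zeros((4, 4, 3))))
        assert np.all(out.raster == 0)

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            tq.to_grayscale(tq.Micrograph(np.zeros((4, 4, 2))))


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        m = tq.Micrograph(np.full((40, 40), 123.0))
        assert np.all(tq.subtract_background(m, 20.0).raster == 0.0)

    def test_compact_blob_peak_retained(self):
        # isolated blob on flat background with sigma much larger than the
        # blob: the subtracted peak stays within 10% of (peak - background)
        img = np.full((128, 128), 30.0)
        yy, xx = np.mgrid[0:128, 0:128]
        img += 100.0 * np.exp(-((xx - 64) ** 2 + (yy - 64) ** 2) / (2 * 3.0**2))
        out = tq.subtract_background(tq.Micrograph(img), 20.0)
        assert abs(out.raster.max() - 100.0) < 10.0

    def test_nonpositive_sigma_rejected(self):
        m = tq.Micrograph(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            tq.subtract_background(m, 0.0)


class TestSmooth:
    def test_constant_image_unchanged(self):
        m = tq.Micrograph(np.full((32, 32), 55.0))
        assert np.allclose(tq.smooth(m, 3.5).raster, 55.0)

    def test_impulse_response_is_gaussian_kernel(self):
        img = np.zeros((65, 65))
        img[32, 32] = 255.0
        out = tq.smooth(tq.Micrograph(img), 2.0).raster
        expected = np.zeros((65, 65))
        expected[32, 32] = 255.0
        expected = ndimage.gaussian_filter(expected, 2.0, mode="reflect")
        assert np.allclose(out, expected)
        assert out.argmax() == img.argmax()

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(7)
        m = tq.Micrograph(rng.uniform(5, 200, (64, 64)))
        out = tq.smooth(m, 3.5)
        rel = abs(out.raster.sum() - m.raster.sum()) / m.raster.sum()
        assert rel < 1e-6

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            tq.smooth(tq.Micrograph(np.zeros((8, 8))), -1.0)


class TestThresholdStats:
    def test_flat_roi_zero_variance(self):
        m = tq.Micrograph(np.full((10, 10), 10.0))
        ts = tq.threshold_stats(m, rect_roi(-0.5, -0.5, 9.4, 9.4))
        assert (ts.l_mean, ts.l_var, ts.l_thresh) == (10.0, 0.0, 10.0)

    def test_two_value_roi_population_variance(self):
        # pixels {8, 12}: mean 10, population variance 4, threshold 14
        m = tq.Micrograph(np.array([[8.0, 12.0], [8.0, 12.0]]))
        ts = tq.threshold_stats(m, rect_roi(-0.5, -0.5, 1.4, 1.4))
        assert (ts.l_mean, ts.l_var, ts.l_thresh) == (10.0, 4.0, 14.0)

    def test_threshold_minus_mean_equals_variance_on_random_rois(self):
        rng = np.random.default_rng(42)
        m = tq.Micrograph(rng.uniform(0, 255, (64, 64)))
        for _ in range(100):
            x0, y0 = rng.uniform(0, 40, 2)
            w, h = rng.uniform(3, 20, 2)
            roi = rect_roi(x0, y0, x0 + w, y0 + h)
            ts = tq.threshold_stats(m, roi)
            assert ts.l_thresh == ts.l_mean + ts.l_var  # exact by construction
            assert ts.l_var >= 0

    def test_constant_shift_moves_mean_not_variance(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(10, 100, (32, 32))
        roi = rect_roi(2, 2, 28, 28)
        t0 = tq.threshold_stats(tq.Micrograph(base), roi)
        t1 = tq.threshold_stats(tq.Micrograph(base + 25.0), roi)
        assert t1.l_mean == pytest.approx(t0.l_mean + 25.0)
        assert t1.l_var == pytest.approx(t0.l_var)

    def test_measurement_roi_and_empty_roi_rejected(self):
        m = tq.Micrograph(np.zeros((16, 16)))
        with pytest.raises(ValueError, match="not a background"):
            tq.threshold_stats(m, rect_roi(1, 1, 10, 10, purpose="measurement"))
        with pytest.raises(ValueError, match="bounds"):
            tq.threshold_stats(m, rect_roi(1, 1, 40, 40))
        tiny = tq.RoiSpec("t", "ipsi", ((5.1, 5.1), (5.3, 5.1), (5.3, 5.3)), "background")
        with pytest.raises(ValueError, match="fewer than 2"):
            tq.threshold_stats(m, tiny)


class TestBinarize:
    def test_all_below_threshold_gives_empty_mask(self):
        m = tq.Micrograph(np.full((8, 8), 10.0))
        mask = tq.binarize(m, tq.ThresholdStats(10.0, 0.0))
        assert not mask.mask.any()  # strict ">" at the threshold

    def test_idempotent_on_scaled_binary_image(self):
        rng = np.random.default_rng(1)
        m = tq.Micrograph(rng.uniform(0, 255, (32, 32)))
        t = tq.ThresholdStats(100.0, 20.0)
        mask1 = tq.binarize(m, t)
        remask = tq.binarize(tq.Micrograph(mask1.mask * 255.0), t)
        assert np.array_equal(mask1.mask, remask.mask)

    def test_raising_threshold_never_adds_foreground(self):
        rng = np.random.default_rng(2)
        m = tq.Micrograph(rng.uniform(0, 255, (32, 32)))
        lo = tq.binarize(m, tq.ThresholdStats(50.0, 10.0))
        hi = tq.binarize(m, tq.ThresholdStats(50.0, 60.0))
        assert not (hi.mask & ~lo.mask).any()


class TestContours:
    def test_filled_square_gives_one_closed_contour(self):
        arr = np.zeros((40, 40), bool)
        arr[10:20, 10:20] = True
        cs = tq.extract_contours(tq.BinaryMask(arr, 0))
        assert len(cs) == 1
        assert cs[0].closed
        assert cs[0].enclosed_area == 100

    def test_two_disjoint_squares_give_two_contours_largest_first(self):
        arr = np.zeros((40, 40), bool)
        arr[5:12, 5:12] = True
        arr[25:35, 20:34] = True
        cs = tq.extract_contours(tq.BinaryMask(arr, 0))
        assert len(cs) == 2
        assert cs[0].enclosed_area > cs[1].enclosed_area

    def test_all_background_mask_gives_empty_list(self):
        cs = tq.extract_contours(tq.BinaryMask(np.zeros((10, 10), bool), 0))
        assert cs == []

    def test_speckle_below_min_area_suppressed(self):
        arr = np.zeros((20, 20), bool)
        arr[3, 3] = True  # 1-px speckle
        arr[8:12, 8:12] = True
        cs = tq.extract_contours(tq.BinaryMask(arr, 0), min_area=5)
        assert len(cs) == 1

    def test_rasterized_contour_reproduces_component_mask(self):
        arr = np.zeros((50, 50), bool)
        arr[12:30, 8:25] = True
        arr[20:26, 30:44] = True
        cs = tq.extract_contours(tq.BinaryMask(arr, 0))
        refill = np.zeros((50, 50), bool)
        for c in cs:
            refill |= tq.rasterize_contour(c, (50, 50))
        assert np.array_equal(refill, arr)

    def test_injection_overlap_is_mask_intersection(self):
        # overlap shading of two case outlines equals the AND of their masks
        a = np.zeros((30, 30), bool); a[5:20, 5:20] = True
        b = np.zeros((30, 30), bool); b[12:28, 12:28] = True
        ca = tq.extract_contours(tq.BinaryMask(a, 0))[0]
        cb = tq.extract_contours(tq.BinaryMask(b, 0))[0]
        overlap = tq.rasterize_contour(ca, (30, 30)) & tq.rasterize_contour(cb, (30, 30))
        assert np.array_equal(overlap, a & b)


def test_load_rois_json_and_yaml(tmp_path):
    rec = '[{"name": "M2", "hemisphere": "contra", "purpose": "measurement", "polygon": [[0,0],[9,0],[9,9]]}]'
    pj = tmp_path / "rois.json"
    pj.write_text(rec)
    py = tmp_path / "rois.yaml"
    py.write_text("- name: M2\n  hemisphere: contra\n  polygon: [[0,0],[9,0],[9,9]]\n")
    for path in (pj, py):
        (roi,) = tq.load_rois(path)
        assert roi.name == "M2" and roi.hemisphere == "contra"
        assert len(roi.polygon) == 3


def test_micrograph_rejects_out_of_range_and_empty():
    with pytest.raises(ValueError):
        tq.Micrograph(np.array([[300.0]]))
    with pytest.raises(ValueError):
        tq.Micrograph(np.zeros((0, 4)))
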