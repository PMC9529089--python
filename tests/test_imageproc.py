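"""Unit tests for the image-processing stages."""

import numpy as np
import pytest

from giftdiam.errors import InvalidParameterError
from giftdiam.imageproc import (
    column_maxima,
    crop_top,
    gap_distances,
    line_opening,
    make_rotation_stack,
    percent_threshold,
    quantize_gradient,
    sobel_magnitude,
    to_gray8,
)

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T


def sobel_oracle(img):
    """Direct 3x3 convolution with replicated borders."""
    f = np.pad(np.asarray(img, dtype=float), 1, mode="edge")
    h, w = img.shape
    gx = np.zeros((h, w))
    gy = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            win = f[r : r + 3, c : c + 3]
            # correlation with the flipped kernel == convolution
            gx[r, c] = np.sum(win * SOBEL_X[::-1, ::-1])
            gy[r, c] = np.sum(win * SOBEL_Y[::-1, ::-1])
    return np.hypot(gx, gy)


class TestToGray8:
    def test_uint8_identity(self):
        img = np.arange(25, dtype=np.uint8).reshape(5, 5)
        np.testing.assert_array_equal(to_gray8(img), img)

    def test_constant_16bit_maps_to_zero(self):
        img = np.full((6, 6), 500, dtype=np.uint16)
        out = to_gray8(img)
        assert out.dtype == np.uint8
        assert np.all(out == 0)

    def test_16bit_minmax_rescale(self):
        img = np.zeros((4, 4), dtype=np.uint16)
        img[0, 0] = 1000
        img[0, 1] = 500
        out = to_gray8(img)
        assert out[0, 0] == 255
        assert out[0, 1] == 128  # rounds 127.5 -> 128
        assert out[3, 3] == 0

    def test_equal_rgb_channels(self):
        img = np.full((5, 5, 3), 100, dtype=np.uint8)
        out = to_gray8(img)
        assert out.dtype == np.uint8
        assert np.all(out == 100)

    @pytest.mark.parametrize("bad", [np.zeros(10), np.zeros((2, 5)), np.zeros((5, 2))])
    def test_rejects_bad_shapes(self, bad):
        with pytest.raises(InvalidParameterError):
            to_gray8(bad.astype(np.uint8))


class TestCropTop:
    def test_keeps_top_rows(self):
        img = np.arange(12, dtype=np.uint8).reshape(4, 3)
        out = crop_top(img, 2)
        np.testing.assert_array_equal(out, img[:2])

    def test_identity_when_keeping_all(self):
        img = np.arange(12, dtype=np.uint8).reshape(4, 3)
        np.testing.assert_array_equal(crop_top(img, 4), img)

    def test_single_row(self):
        img = np.arange(12, dtype=np.uint8).reshape(4, 3)
        np.testing.assert_array_equal(crop_top(img, 1), img[:1])

    def test_too_many_rows_rejected(self):
        with pytest.raises(InvalidParameterError):
            crop_top(np.zeros((4, 3), dtype=np.uint8), 5)


class TestSobel:
    def test_flat_field_zero(self):
        assert np.all(sobel_magnitude(np.full((8, 8), 37.0)) == 0)

    def test_vertical_step_localized(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 255.0
        mag = sobel_magnitude(img)
        # strongest response in the two columns adjacent to the step
        peak_cols = {4, 5}
        assert set(np.flatnonzero(mag[5] == mag[5].max())) == peak_cols
        assert np.all(mag[:, :3] == 0) and np.all(mag[:, 8:] == 0)

    def test_matches_direct_convolution(self, rng):
        img = rng.integers(0, 256, size=(9, 9)).astype(float)
        np.testing.assert_allclose(sobel_magnitude(img), sobel_oracle(img), atol=1e-9)

    def test_single_bright_pixel_neighborhood(self):
        img = np.zeros((9, 9))
        img[4, 4] = 255.0
        np.testing.assert_allclose(sobel_magnitude(img), sobel_oracle(img), atol=1e-9)


class TestPercentThreshold:
    def test_full_inclusion_at_100(self, rng):
        grad = rng.random((10, 10)) + 0.5
        assert percent_threshold(grad, 100.0).all()

    def test_top_k_on_distinct_values(self, rng):
        grad = rng.permutation(np.arange(1.0, 101.0)).reshape(10, 10)
        mask = percent_threshold(grad, 10.0)
        expected = grad > np.sort(grad, axis=None)[-10 - 1]
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 10

    def test_all_equal_values_single_tie_class(self):
        grad = np.full((10, 10), 3.3)
        assert percent_threshold(grad, 5.0).all()

    def test_zero_gradient_never_edge(self):
        grad = np.zeros((10, 10))
        assert not percent_threshold(grad, 5.0).any()

    @pytest.mark.parametrize("p", [0.0, -1.0, 101.0])
    def test_invalid_percent_rejected(self, p):
        with pytest.raises(InvalidParameterError):
            percent_threshold(np.ones((5, 5)), p)


class TestQuantizeGradient:
    def test_saturates_at_255(self):
        grad = np.array([[0.0, 100.4, 255.0], [300.0, 1020.0, 7.6]])
        out = quantize_gradient(grad)
        assert out.dtype == np.uint8
        np.testing.assert_array_equal(out, [[0, 100, 255], [255, 255, 8]])


class TestRotationStack:
    @pytest.mark.parametrize(
        "step,expected", [(90, 2), (45, 4), (30, 6), (18, 10), (12, 15), (6, 30)]
    )
    def test_copy_count_law(self, step, expected, rng):
        mask = rng.random((16, 16)) > 0.8
        stack = make_rotation_stack(mask, step)
        assert len(stack) == expected
        np.testing.assert_allclose(
            stack.angles_deg, [k * step for k in range(expected)]
        )

    def test_copy_zero_is_input(self, rng):
        mask = rng.random((16, 16)) > 0.8
        stack = make_rotation_stack(mask, 45)
        np.testing.assert_array_equal(stack.copies[0], mask)
        assert stack.valid_regions[0].all()

    def test_90_degrees_is_exact_rotation(self, rng):
        mask = rng.random((12, 20)) > 0.7
        stack = make_rotation_stack(mask, 90)
        copy = stack.copies[1]
        valid = stack.valid_regions[1]
        assert valid.all()  # axis-aligned rotation has no padding
        np.testing.assert_array_equal(copy, np.rot90(mask))

    def test_invalid_step_rejected(self):
        with pytest.raises(InvalidParameterError):
            make_rotation_stack(np.zeros((5, 5), dtype=bool), 50)

    def test_padding_marked_invalid(self):
        mask = np.ones((20, 20), dtype=bool)
        stack = make_rotation_stack(mask, 45)
        valid = stack.valid_regions[1]
        assert not valid[0, 0]  # corner of expanded canvas is padding
        assert valid[valid.shape[0] // 2, valid.shape[1] // 2]
        assert not stack.copies[1][0, 0]  # padding is non-edge


def opening_oracle(mask, length):
    """Union of every horizontal length-L line placement fully inside mask."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    for r in range(h):
        for c in range(w - length + 1):
            if mask[r, c : c + length].all():
                out[r, c : c + length] = True
    return out


class TestLineOpening:
    def test_run_of_exact_length_preserved(self):
        mask = np.zeros((5, 20), dtype=bool)
        mask[2, 4:12] = True
        np.testing.assert_array_equal(line_opening(mask, 8), mask)

    def test_shorter_run_removed(self):
        mask = np.zeros((5, 20), dtype=bool)
        mask[2, 4:11] = True  # 7 px < 8
        assert not line_opening(mask, 8).any()

    def test_vertical_line_removed(self):
        mask = np.zeros((30, 20), dtype=bool)
        mask[:, 10] = True
        assert not line_opening(mask, 8).any()

    @pytest.mark.parametrize("length", [2, 3, 5, 8])
    def test_equals_placement_oracle(self, length, rng):
        for _ in range(20):
            mask = rng.random((16, 24)) > 0.5
            np.testing.assert_array_equal(
                line_opening(mask, length), opening_oracle(mask, length)
            )

    def test_idempotent_and_antiextensive(self, rng):
        mask = rng.random((32, 32)) > 0.45
        opened = line_opening(mask, 6)
        np.testing.assert_array_equal(line_opening(opened, 6), opened)
        assert not (opened & ~mask).any()

    def test_length_one_is_identity(self, rng):
        mask = rng.random((8, 8)) > 0.5
        np.testing.assert_array_equal(line_opening(mask, 1), mask)


class TestColumnMaxima:
    @staticmethod
    def positions_of(mask, valid=None, col=None):
        cols, rows = column_maxima(mask, valid)
        if col is None:
            return cols, rows
        return list(rows[cols == col])

    def test_isolated_pixels(self):
        mask = np.zeros((40, 3), dtype=bool)
        mask[10, 1] = mask[30, 1] = True
        assert self.positions_of(mask, col=1) == [10, 30]

    def test_run_center(self):
        mask = np.zeros((20, 3), dtype=bool)
        mask[10:13, 0] = True  # rows 10-12
        assert self.positions_of(mask, col=0) == [11]

    def test_even_run_rounds_toward_top(self):
        mask = np.zeros((20, 3), dtype=bool)
        mask[10:12, 2] = True  # rows 10-11 -> 10
        assert self.positions_of(mask, col=2) == [10]

    def test_empty_column(self):
        mask = np.zeros((10, 4), dtype=bool)
        cols, rows = column_maxima(mask)
        assert cols.size == 0 and rows.size == 0

    def test_runs_touching_invalid_discarded(self):
        mask = np.zeros((20, 1), dtype=bool)
        mask[5:8, 0] = True
        mask[14, 0] = True
        valid = np.ones((20, 1), dtype=bool)
        valid[8, 0] = False  # immediately below the first run
        assert self.positions_of(mask, valid, col=0) == [14]

    def test_results_sorted_by_column_then_row(self, rng):
        mask = rng.random((30, 30)) > 0.7
        cols, rows = column_maxima(mask)
        order = np.lexsort((rows, cols))
        np.testing.assert_array_equal(cols, cols[order])
        np.testing.assert_array_equal(rows, rows[order])


class TestGapDistances:
    def test_consecutive_differences(self):
        cols = np.array([0, 0, 0])
        rows = np.array([10, 30, 55])
        np.testing.assert_allclose(sorted(gap_distances(cols, rows)), [20, 25])

    def test_physical_scaling(self):
        d = gap_distances(np.array([0, 0]), np.array([10, 30]), 32.25)
        np.testing.assert_allclose(d, [20 / 32.25])
        assert abs(d[0] - 0.620) < 1e-3

    def test_single_position_columns_contribute_nothing(self):
        cols = np.array([0, 1, 2])
        rows = np.array([5, 9, 11])
        assert gap_distances(cols, rows).size == 0

    def test_min_gap_floor(self):
        cols = np.zeros(4, dtype=int)
        rows = np.array([0, 2, 5, 30])
        np.testing.assert_allclose(
            sorted(gap_distances(cols, rows, min_gap_px=3)), [3, 25]
        )

    def test_scale_linearity(self, rng):
        cols = np.repeat(np.arange(5), 4)
        rows = np.sort(rng.integers(0, 100, size=20).reshape(5, 4), axis=1).ravel()
        d1 = gap_distances(cols, rows, 1.0)
        d2 = gap_distances(cols, rows, 2.0)
        np.testing.assert_allclose(d1, 2.0 * d2)
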