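"""Preprocessing: projection, drift correction, blur, triangle threshold."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift
from scipy.signal import convolve2d

from protrudyn.errors import (
    DegenerateInputError,
    DimensionalityError,
    ParameterError,
)
from protrudyn.imgpipe import (
    TimelapseStack,
    binarize_and_outline,
    correct_drift,
    gaussian_lowpass,
    max_z_project,
    mask_outline,
    triangle_threshold,
)


def _stack(data, px=0.06, dt=5.0):
    return TimelapseStack(data=data, pixel_size=px, frame_interval=dt)


class TestMaxZProject:
    def test_single_plane_is_identity(self):
        rng = np.random.default_rng(0)
        data = rng.random((3, 1, 10, 12))
        out = max_z_project(_stack(data))
        np.testing.assert_array_equal(out.data, data[:, 0])

    def test_dominating_plane_wins(self):
        data = np.ones((2, 4, 9, 9))
        data[:, 2] = 7.0
        out = max_z_project(_stack(data))
        np.testing.assert_array_equal(out.data, data[:, 2])

    def test_matches_exhaustive_loop_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.random((4, 3, 8, 9))
        out = max_z_project(_stack(data)).data
        for t in range(4):
            for y in range(8):
                for x in range(9):
                    expected = max(data[t, z, y, x] for z in range(3))
                    assert out[t, y, x] == expected

    def test_projected_stack_rejected(self):
        with pytest.raises(DimensionalityError):
            max_z_project(_stack(np.zeros((2, 9, 9))))

    def test_metadata_preserved(self):
        out = max_z_project(_stack(np.zeros((2, 2, 9, 9)), px=0.088, dt=2.5))
        assert out.pixel_size == 0.088 and out.frame_interval == 2.5


def _textured_frame(rng, shape=(48, 64)):
    frame = rng.random(shape)
    return gaussian_lowpass(frame, 3.0)  # band-limit so correlation peaks


class TestCorrectDrift:
    def test_identical_frames_zero_offsets(self):
        rng = np.random.default_rng(1)
        frame = _textured_frame(rng)
        frames = np.stack([frame] * 4)
        aligned, trace = correct_drift(frames)
        np.testing.assert_array_equal(trace.offsets, 0.0)
        np.testing.assert_array_equal(aligned, frames)

    def test_integer_shift_recovered_and_undone(self):
        rng = np.random.default_rng(2)
        base = _textured_frame(rng)
        drifted = np.roll(base, (3, -2), axis=(0, 1))
        aligned, trace = correct_drift(np.stack([base, drifted]))
        np.testing.assert_allclose(trace.offsets[1], [3.0, -2.0])
        # round trip: correction restores the original frame
        assert np.abs(aligned[1] - base).mean() < 0.01 * np.ptp(base)

    def test_subpixel_shift_recovered_within_half_pixel(self):
        rng = np.random.default_rng(3)
        base = _textured_frame(rng)
        shifted = np.fft.ifftn(
            fourier_shift(np.fft.fftn(base), (0.5, 0.0))
        ).real
        _, trace = correct_drift(np.stack([base, shifted]), upsample_factor=20)
        assert abs(trace.offsets[1, 0] - 0.5) <= 0.5
        assert abs(trace.offsets[1, 1]) <= 0.5

    def test_constant_frame_warns_and_assumes_zero(self):
        rng = np.random.default_rng(4)
        frames = np.stack([_textured_frame(rng), np.zeros((48, 64))])
        with pytest.warns(UserWarning, match="constant"):
            _, trace = correct_drift(frames)
        np.testing.assert_array_equal(trace.offsets[1], 0.0)


class TestGaussianLowpass:
    def test_constant_frame_unchanged(self):
        frame = np.full((20, 20), 3.5)
        np.testing.assert_allclose(gaussian_lowpass(frame), frame)

    def test_point_source_symmetric_and_conserved(self):
        frame = np.zeros((41, 41))
        frame[20, 20] = 100.0
        out = gaussian_lowpass(frame, 2.0)
        np.testing.assert_allclose(out, out[::-1, :])
        np.testing.assert_allclose(out, out[:, ::-1])
        np.testing.assert_allclose(out.sum(), 100.0, rtol=1e-3)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        frame = rng.random((32, 40)) * 50
        sigma = 2.0
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        kernel = np.outer(g, g)
        padded = np.pad(frame, radius, mode="symmetric")
        expected = convolve2d(padded, kernel, mode="valid")
        out = gaussian_lowpass(frame, sigma)
        assert np.abs(out - expected).max() < 1e-6 * np.ptp(frame)

    def test_non_positive_kernel_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_lowpass(np.zeros((9, 9)), 0.0)


def triangle_bin_oracle(hist):
    """Exhaustive point-to-chord search over all bins (independent oracle)."""
    hist = np.asarray(hist, dtype=float)
    nz = np.flatnonzero(hist)
    peak = int(np.argmax(hist))
    first, last = int(nz[0]), int(nz[-1])
    end = last if (last - peak) >= (peak - first) else first
    x0, y0, x1, y1 = peak, hist[peak], end, hist[end]
    norm = np.hypot(x1 - x0, y1 - y0)
    best_bin, best_dist = peak, -1.0
    order = sorted(range(min(peak, end), max(peak, end) + 1),
                   key=lambda b: abs(b - peak))
    for b in order:
        d = abs((y1 - y0) * b - (x1 - x0) * hist[b] + x1 * y0 - y1 * x0) / norm
        if d > best_dist:
            best_bin, best_dist = b, d
    return best_bin, end >= peak


class TestTriangleThreshold:
    def test_two_value_image_separated(self):
        rng = np.random.default_rng(6)
        frame = np.full((50, 50), 10.0)
        fg = rng.random((50, 50)) < 0.1
        frame[fg] = 200.0
        level = triangle_threshold(frame)
        assert 10.0 < level < 200.0
        np.testing.assert_array_equal(frame >= level, fg)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_chord_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 1000, size=256).astype(float)
        hist[rng.integers(0, 256)] += 5000  # pronounced peak
        level = triangle_threshold(histogram=hist, value_range=(0.0, 256.0))
        best_bin, right_tail = triangle_bin_oracle(hist)
        expected = (best_bin + 1.0) if right_tail else float(best_bin)
        assert level == pytest.approx(expected)

    def test_inversion_consistency(self):
        rng = np.random.default_rng(7)
        frame = np.concatenate(
            [rng.normal(20, 2, 4000), rng.normal(200, 8, 500)]
        ).reshape(45, 100)
        level = triangle_threshold(frame)
        inverted = frame.min() + frame.max() - frame
        level_inv = triangle_threshold(inverted)
        np.testing.assert_array_equal(frame >= level, inverted <= level_inv)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        frame = np.concatenate(
            [rng.normal(20, 2, 4000), rng.normal(200, 8, 500)]
        ).reshape(45, 100)
        level = triangle_threshold(frame)
        for c in (0.5, 3.0, 117.0):
            scaled = triangle_threshold(frame * c)
            assert scaled == pytest.approx(level * c, rel=1e-9)

    def test_constant_frame_rejected(self):
        with pytest.raises(DegenerateInputError):
            triangle_threshold(np.full((10, 10), 7.0))


class TestBinarizeAndOutline:
    def test_outline_matches_neighborhood_scan_oracle(self):
        rng = np.random.default_rng(9)
        mask = gaussian_lowpass(rng.random((30, 30)), 2.0) > 0.5
        outline = mask_outline(mask)
        h, w = mask.shape
        for y in range(h):
            for x in range(w):
                if not mask[y, x]:
                    assert not outline[y, x]
                    continue
                boundary = any(
                    0 <= y + dy < h and 0 <= x + dx < w
                    and not mask[y + dy, x + dx]
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                )
                assert outline[y, x] == boundary

    def test_single_frame_overlay_first_hue(self):
        frame = np.zeros((12, 12))
        frame[4:8, 4:8] = 10.0
        series, overlay = binarize_and_outline(frame[None], np.array([5.0]))
        outline = mask_outline(series.masks[0])
        assert (overlay[outline] == np.array([1.0, 0.0, 0.0])).all()
        assert overlay[~outline].sum() == 0.0

    def test_largest_component_kept(self):
        frame = np.zeros((20, 20))
        frame[2:12, 2:12] = 10.0  # dendrite
        frame[16:18, 16:18] = 10.0  # debris
        series, _ = binarize_and_outline(frame[None], np.array([5.0]))
        assert series.masks[0, 3, 3] and not series.masks[0, 16, 16]

    def test_empty_mask_flagged(self):
        frames = np.zeros((2, 10, 10))
        frames[0, 4, 4] = 10.0
        series, _ = binarize_and_outline(frames, np.array([5.0, 5.0]))
        assert series.empty_frames == [1]


class TestTimelapseStack:
    def test_rejects_tiny_spatial_dims(self):
        with pytest.raises(DimensionalityError):
            _stack(np.zeros((2, 4, 4)))

    def test_rejects_bad_calibration(self):
        with pytest.raises(ParameterError):
            _stack(np.zeros((2, 9, 9)), px=0.0)
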