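"""Boundary tracing, thresholding and cardiac-phase detection."""

import numpy as np
import pytest

from camwall import (
    PixelSeries,
    VideoStack,
    binarize,
    detect_cardiac_phases,
    suggest_threshold,
    systole_diastole_overlay,
    trace_boundary,
)

from conftest import brute_force_boundary_sets


def _mask_from_rows(rows):
    return np.array([[ch == "#" for ch in row] for row in rows], dtype=bool)


class TestBinarize:
    def test_dark_pixels_selected(self):
        frame = np.array([[10, 200], [99, 100]], dtype=np.uint8)
        np.testing.assert_array_equal(
            binarize(frame, 100), [[True, False], [True, False]]
        )

    def test_threshold_range_checked(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2), dtype=np.uint8), 300)

    def test_largest_only_keeps_biggest_object(self):
        frame = np.full((5, 5), 200, dtype=np.uint8)
        frame[0, 0] = 0  # single dark pixel
        frame[2:5, 2:5] = 0  # 3x3 dark block
        mask = binarize(frame, 100, largest_only=True)
        assert mask.sum() == 9
        assert not mask[0, 0]

    def test_min_area_drops_specks(self):
        frame = np.full((5, 5), 200, dtype=np.uint8)
        frame[0, 0] = 0
        frame[2:4, 2:4] = 0
        mask = binarize(frame, 100, min_area=2)
        assert mask.sum() == 4 and not mask[0, 0]

    def test_fill_holes_closes_lumen(self):
        frame = np.full((5, 5), 200, dtype=np.uint8)
        frame[1:4, 1:4] = 0
        frame[2, 2] = 200  # bright hole
        mask = binarize(frame, 100, fill_holes=True)
        assert mask[2, 2]

    def test_otsu_separates_bimodal_frame(self):
        frame = np.full((10, 10), 180, dtype=np.uint8)
        frame[:, :4] = 60
        frame[:, 4] = 120  # blurred wall column between the two populations
        thr = suggest_threshold(frame)
        assert 60 < thr < 180
        with pytest.raises(ValueError):
            suggest_threshold(np.full((5, 5), 7, dtype=np.uint8))


class TestMooreTracing:
    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        (trace,) = trace_boundary(mask)
        assert trace.as_set() == {(1, 1)}

    def test_filled_square_boundary_is_its_perimeter(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        (trace,) = trace_boundary(mask)
        assert len(trace) == 8  # 3x3 square: all but the center
        assert trace.as_set() == {
            (r, c) for r in range(1, 4) for c in range(1, 4) if (r, c) != (2, 2)
        }

    def test_diagonal_pair_traced_as_one_object(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        traces = trace_boundary(mask)
        assert len(traces) == 1
        assert traces[0].as_set() == {(1, 1), (2, 2)}

    def test_inner_corner_pixels_are_visited(self):
        # the junction pixel of a T-shape is only exposed across a cut corner
        mask = _mask_from_rows(
            [
                ".....",
                ".###.",
                "..#..",
                "..#..",
                ".....",
            ]
        )
        (trace,) = trace_boundary(mask)
        assert trace.as_set() == brute_force_boundary_sets(mask)[0]

    def test_consecutive_points_are_8_neighbors(self):
        rng = np.random.default_rng(11)
        mask = rng.random((12, 12)) < 0.45
        for trace in trace_boundary(mask):
            diffs = np.abs(np.diff(trace.points, axis=0))
            assert np.all(diffs.max(axis=1) <= 1)
            wrap = np.abs(trace.points[0] - trace.points[-1])
            assert wrap.max() <= 1

    def test_empty_mask_and_start_pixel(self):
        assert trace_boundary(np.zeros((4, 4), dtype=bool)) == []
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        (trace,) = trace_boundary(mask, start=(2, 2))
        assert tuple(trace.points[0]) == (2, 2)
        with pytest.raises(ValueError):
            trace_boundary(mask, start=(0, 0))

    @pytest.mark.parametrize("density", [0.2, 0.45, 0.7])
    def test_matches_brute_force_boundary_definition(self, density):
        rng = np.random.default_rng(int(density * 100))
        for _ in range(60):
            mask = rng.random((16, 16)) < density
            got = [t.as_set() for t in trace_boundary(mask)]
            want = brute_force_boundary_sets(mask)
            assert got == want

    def test_translation_equivariance(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            mask = np.zeros((20, 20), dtype=bool)
            mask[2:10, 2:10] = rng.random((8, 8)) < 0.5
            base = [t.as_set() for t in trace_boundary(mask)]
            shifted = np.roll(np.roll(mask, 3, axis=0), 5, axis=1)
            moved = [t.as_set() for t in trace_boundary(shifted)]
            assert moved == [{(r + 3, c + 5) for r, c in s} for s in base]


class TestCardiacPhases:
    def _cosine_series(self, f_hz=3.0, fs=120.0, n=360, sign=1.0):
        t = np.arange(n) / fs
        return PixelSeries(sign * 20 * np.cos(2 * np.pi * f_hz * t) + 120, fs)

    def test_period_and_extrema_of_cosine(self):
        phases = detect_cardiac_phases(self._cosine_series())
        assert phases.estimated_period_frames == 40
        assert phases.fundamental_hz == pytest.approx(3.0, abs=120 / 360)
        # brightness minima (default systole) of +cos sit near odd half-periods
        for frame in phases.systolic_frames:
            assert min(abs(frame - k * 20) for k in (1, 3, 5, 7, 9, 11, 13, 15, 17)) <= 2
        assert len(phases.systolic_frames) >= 8

    def test_systole_polarity_switch(self):
        up = detect_cardiac_phases(self._cosine_series(), systole_at="maxima")
        down = detect_cardiac_phases(self._cosine_series())
        assert set(up.systolic_frames) == set(down.diastolic_frames)
        with pytest.raises(ValueError):
            detect_cardiac_phases(self._cosine_series(), systole_at="peaks")

    def test_noise_only_series_rejected(self):
        rng = np.random.default_rng(3)
        series = PixelSeries(rng.normal(120, 1, size=360), 120.0)
        with pytest.raises(ValueError, match="noise floor"):
            detect_cardiac_phases(series)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="two estimated periods"):
            detect_cardiac_phases(self._cosine_series(n=50))


class TestOverlay:
    def test_motionless_stack_gives_identical_boundaries(self):
        frame = np.full((32, 32), 180, dtype=np.uint8)
        frame[10:22, 10:22] = 60
        stack = VideoStack(np.stack([frame] * 20), 120.0)
        phases = detect_cardiac_phases(
            PixelSeries(np.cos(2 * np.pi * np.arange(20) / 5), 120.0),
            fundamental_hz=24.0,
        )
        sys_t, dia_t, overlay = systole_diastole_overlay(stack, phases, 120)
        assert [t.as_set() for t in sys_t] == [t.as_set() for t in dia_t]
        assert overlay.shape == (32, 32, 3)

    def test_dilating_vessel_boundaries_differ(self, dilation_stack, dilation_maps):
        r, c = np.unravel_index(
            np.argmax(dilation_maps.rms_map), dilation_maps.rms_map.shape
        )
        phases = detect_cardiac_phases(
            dilation_stack.pixel_series(int(r), int(c)),
            fundamental_hz=dilation_maps.fundamental_hz,
        )
        thr = suggest_threshold(dilation_stack.frames[phases.late_diastolic_frame])
        sys_t, dia_t, overlay = systole_diastole_overlay(dilation_stack, phases, thr)
        assert sys_t[0].as_set() != dia_t[0].as_set()
        # overlay colors both contours over the grayscale background
        assert (overlay == (40, 90, 255)).all(axis=-1).any()
        assert (overlay == (255, 60, 40)).all(axis=-1).any()
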