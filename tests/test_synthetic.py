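"""Synthetic video generator: waveform math, rendering, determinism."""

import math

import numpy as np
import pytest

from camwall import (
    AcquisitionSpec,
    MotionLaw,
    SyntheticScene,
    VesselGeometry,
    radius_waveform,
    render_frame,
    render_video,
)
from camwall.synthetic_video import (
    _translation_offset,
    ground_truth,
    scene_from_dict,
    scene_to_dict,
    signed_distance_field,
)

from conftest import RADIUS_UM, straight_scene, vertical_centerline


class TestMotionLaw:
    def test_waveform_peak_at_t0(self):
        motion = MotionLaw(3.2, harmonic_amplitudes=(0.1,))
        assert radius_waveform(0.0, motion) == pytest.approx(1.1)

    def test_waveform_mean_over_period_is_one(self):
        motion = MotionLaw(2.0, harmonic_amplitudes=(0.1, 0.05, 0.02))
        t = np.arange(1000) / 1000 * (1 / 2.0)  # one exact period
        assert radius_waveform(t, motion).mean() == pytest.approx(1.0, abs=1e-12)

    def test_waveform_periodicity_with_asymmetry(self):
        motion = MotionLaw(3.2, harmonic_amplitudes=(0.1, 0.04), asymmetry=0.6)
        t = np.linspace(0, 1 / 3.2, 257)
        np.testing.assert_allclose(
            radius_waveform(t, motion), radius_waveform(t + 1 / 3.2, motion), atol=1e-12
        )

    def test_asymmetric_upstroke_is_faster(self):
        # with asymmetry > 0 the radius rises to its peak in less time than it
        # takes to relax, so mean positive slope exceeds mean negative magnitude
        motion = MotionLaw(3.2, harmonic_amplitudes=(0.1,), asymmetry=0.5)
        t = np.arange(4096) / 4096 / 3.2
        d = np.diff(radius_waveform(t, motion))
        assert d[d > 0].mean() > -d[d < 0].mean()
        symmetric = MotionLaw(3.2, harmonic_amplitudes=(0.1,))
        d0 = np.diff(radius_waveform(t, symmetric))
        assert d0[d0 > 0].mean() == pytest.approx(-d0[d0 < 0].mean(), rel=1e-2)

    def test_phase_gradient_interpolates_linearly(self):
        motion = MotionLaw(3.2, harmonic_amplitudes=(0.1,), harmonic_phases_deg=((0.0, 90.0),))
        assert motion.phase_rad(1, 0.0) == pytest.approx(0.0)
        assert motion.phase_rad(1, 0.5) == pytest.approx(math.pi / 4)
        assert motion.phase_rad(1, 1.0) == pytest.approx(math.pi / 2)

    def test_harmonic_onset_gates_term(self):
        motion = MotionLaw(2.0, harmonic_amplitudes=(0.0, 0.1), harmonic_onsets_s=(None, 1.0))
        assert radius_waveform(0.0, motion) == pytest.approx(1.0)
        assert radius_waveform(1.0, motion) != pytest.approx(1.0)

    def test_amplitude_sum_must_stay_below_one(self):
        with pytest.raises(ValueError, match="< 1"):
            MotionLaw(3.2, harmonic_amplitudes=(0.6, 0.5))

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            MotionLaw(0.0)
        with pytest.raises(ValueError):
            MotionLaw(3.2, asymmetry=1.0)
        with pytest.raises(ValueError):
            MotionLaw(3.2, harmonic_amplitudes=(-0.1,))
        with pytest.raises(ValueError):
            MotionLaw(3.2, translation_amplitude_um=-1.0)

    def test_translation_direction_convention(self):
        # 0 degrees points along +columns, 90 degrees along -rows (up on screen)
        right = MotionLaw(1.0, translation_amplitude_um=5.0, translation_direction_deg=0.0)
        up = MotionLaw(1.0, translation_amplitude_um=5.0, translation_direction_deg=90.0)
        np.testing.assert_allclose(_translation_offset(0.0, right), [0.0, 5.0], atol=1e-12)
        np.testing.assert_allclose(_translation_offset(0.0, up), [-5.0, 0.0], atol=1e-12)


class TestGeometry:
    def test_needs_two_centerline_points(self):
        with pytest.raises(ValueError):
            VesselGeometry([[0.0, 0.0]], 10.0)

    def test_daughters_must_start_at_parent_endpoint(self):
        with pytest.raises(ValueError, match="parent endpoint"):
            VesselGeometry(
                [[0.0, 0.0], [0.0, 100.0]],
                10.0,
                "bifurcated",
                daughter_centerlines=([[1.0, 1.0], [50.0, 200.0]], [[0.0, 100.0], [-50.0, 200.0]]),
            )

    def test_bifurcation_arclength_continues_through_branch(self):
        geo = VesselGeometry(
            [[0.0, 0.0], [0.0, 100.0]],
            10.0,
            "bifurcated",
            daughter_centerlines=(
                [[0.0, 100.0], [30.0, 140.0]],
                [[0.0, 100.0], [-30.0, 140.0]],
            ),
        )
        offsets = [off for _, _, off in geo.tubes()]
        assert offsets == [0.0, 100.0, 100.0]
        assert geo.total_arclength() == pytest.approx(150.0)


class TestRendering:
    def _flat_scene(self, noise_sigma=0.0, psf_sigma_um=8.0):
        acq = AcquisitionSpec(
            frame_shape=(64, 64), noise_sigma=noise_sigma, psf_sigma_um=psf_sigma_um
        )
        return SyntheticScene(
            geometry=VesselGeometry(vertical_centerline(acq), RADIUS_UM, "straight"),
            motion=MotionLaw(3.2),
            acquisition=acq,
            rng_seed=0,
        )

    def test_intensity_extremes_inside_and_outside(self):
        scene = self._flat_scene()
        frame = render_frame(scene, 0.0)
        rho = signed_distance_field(scene, 0.0)
        acq = scene.acquisition
        assert np.all(frame[rho < -5 * acq.psf_sigma_um] == acq.vessel_intensity)
        assert np.all(frame[rho > 5 * acq.psf_sigma_um] == acq.background_intensity)
        # the exact wall sits midway between the two gray levels
        mid = (acq.vessel_intensity + acq.background_intensity) / 2
        near_wall = frame[np.abs(rho) < 0.05 * acq.psf_sigma_um]
        assert np.all(np.abs(near_wall.astype(float) - mid) <= 2)

    def test_dark_pixel_area_matches_analytic_width(self):
        # noise-free straight vessel: pixels darker than the midpoint span the
        # true lumen width (2 R / pitch) per row, within a half-pixel per edge
        scene = self._flat_scene()
        frame = render_frame(scene, 0.0)
        acq = scene.acquisition
        mid = (acq.vessel_intensity + acq.background_intensity) / 2
        dark = (frame < mid).sum()
        expected = (2 * RADIUS_UM / acq.pixel_pitch_um) * acq.frame_shape[0]
        assert dark == pytest.approx(expected, rel=0.02)

    def test_zero_psf_renders_hard_edge(self):
        frame = render_frame(self._flat_scene(psf_sigma_um=0.0), 0.0)
        assert set(np.unique(frame)) == {60, 180}

    def test_time_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_frame(self._flat_scene(), t=10.0)

    def test_rendering_is_seed_deterministic(self):
        acq = AcquisitionSpec(frame_shape=(32, 32), duration_s=0.1)
        a = render_video(straight_scene(MotionLaw(3.2, (0.05,)), seed=9, acq=acq))
        b = render_video(straight_scene(MotionLaw(3.2, (0.05,)), seed=9, acq=acq))
        c = render_video(straight_scene(MotionLaw(3.2, (0.05,)), seed=10, acq=acq))
        np.testing.assert_array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_frames_reproducible_in_any_order(self):
        scene = straight_scene(
            MotionLaw(3.2, (0.05,)), seed=4, acq=AcquisitionSpec(frame_shape=(32, 32), duration_s=0.1)
        )
        stack = render_video(scene)
        lone = render_frame(scene, 5 / 120.0, frame_index=5)
        np.testing.assert_array_equal(stack.frames[5], lone)

    def test_default_acquisition_yields_360_frames(self, dilation_stack):
        assert AcquisitionSpec().n_frames == 360
        assert dilation_stack.n_frames == 360


class TestGroundTruthAndSerialization:
    def test_ground_truth_tracks_waveform(self, dilation_scene):
        gt = ground_truth(dilation_scene)
        assert len(gt) == 360
        assert gt["wall_radius_um"].iloc[0] == pytest.approx(RADIUS_UM * 1.09)
        times = gt["time_s"].to_numpy()
        np.testing.assert_allclose(np.diff(times), 1 / 120.0)

    def test_scene_dict_round_trip(self, gradient_scene):
        restored = scene_from_dict(scene_to_dict(gradient_scene))
        assert scene_to_dict(restored) == scene_to_dict(gradient_scene)

    def test_scene_dict_round_trip_with_onsets(self, gated_scene):
        restored = scene_from_dict(scene_to_dict(gated_scene))
        stack_a = render_frame(restored, 0.0, 0)
        stack_b = render_frame(gated_scene, 0.0, 0)
        np.testing.assert_array_equal(stack_a, stack_b)
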