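import numpy as np
import pytest

import thermogate as tg
from thermogate.synthetic import (
    dataset_a_scenarios,
    dataset_b_scenarios,
    load_manifest,
    load_scenario,
    make_dataset,
    roi_geometry,
)


class TestBreathingWaveform:
    def test_single_segment_peak_count_and_spacing(self):
        gt = tg.breathing_waveform(tg.ProtocolConfig(((30.0, 20.0),)), fps=10.0)
        assert len(gt.ref_peaks) == 10
        assert np.allclose(np.diff(gt.ref_peaks.peak_times), 3.0)

    def test_phase_continuity_at_segment_boundary(self):
        gt = tg.breathing_waveform(tg.ProtocolConfig(((60.0, 20.0), (60.0, 10.0))), 10.0)
        w = gt.waveform.values
        # largest sample-to-sample step near the boundary is no larger than
        # the steepest slope of either segment: no jump from the rate switch
        max_slope = 2 * np.pi * (20 / 60) / 10.0  # radians/sample at 20 bpm
        assert np.abs(np.diff(w[595:605])).max() <= max_slope * 1.01

    def test_full_protocol_peak_count(self):
        gt = tg.breathing_waveform(tg.ProtocolConfig(), fps=10.0)
        assert len(gt.ref_peaks) == 80  # 20 + 10 + 30 + 20 breaths

    def test_peaks_coincide_with_waveform_maxima(self):
        gt = tg.breathing_waveform(tg.ProtocolConfig(((40.0, 15.0),)), fps=10.0)
        idx = np.round(gt.ref_peaks.peak_times * 10).astype(int)
        for i in idx[1:-1]:
            window = gt.waveform.values[i - 2 : i + 3]
            assert window.max() >= gt.waveform.values.max() - 1e-3

    def test_programmed_rate_is_piecewise(self):
        gt = tg.breathing_waveform(tg.ProtocolConfig(), fps=10.0)
        assert gt.programmed_rate(np.array([30.0]))[0] == 20.0
        assert gt.programmed_rate(np.array([90.0]))[0] == 10.0
        assert gt.programmed_rate(np.array([150.0]))[0] == 30.0
        assert gt.programmed_rate(np.array([210.0]))[0] == 20.0

    def test_rate_outside_band_rejected(self):
        with pytest.raises(ValueError):
            tg.ProtocolConfig(((60.0, 55.0),))


class TestRoiGeometry:
    def test_mask_anchor_at_reference_distance(self):
        layout = roi_geometry("mask", 10.0)
        assert len(layout.roi_pixels) == 12
        assert layout.amp_scale == 1.0

    def test_inverse_square_scaling(self):
        layout = roi_geometry("mask", 20.0)
        assert len(layout.roi_pixels) == 3  # 12 / 4

    def test_subpixel_nostril_is_amplitude_diluted(self):
        layout = roi_geometry("nostril", 30.0)
        assert len(layout.roi_pixels) == 1
        assert layout.amp_scale == pytest.approx(2 * (10 / 30) ** 2)
        assert layout.amp_scale < 1.0

    def test_roi_is_subset_of_body_and_on_grid(self):
        for dist in (5, 10, 30, 60, 150):
            layout = roi_geometry("mask", dist)
            body = {tuple(p) for p in layout.body_pixels}
            roi = {tuple(p) for p in layout.roi_pixels}
            assert roi <= body
            assert all(0 <= r < 8 and 0 <= c < 8 for r, c in body)

    def test_too_close_rejected(self):
        with pytest.raises(ValueError):
            roi_geometry("mask", 3.0)


class TestRenderVideo:
    def test_noise_free_render_matches_closed_form_mean(self):
        scene = tg.SceneConfig(noise_sd=0.0, quant_step=0.0, distance_cm=10.0)
        protocol = tg.ProtocolConfig(((30.0, 20.0),))
        video, gt = tg.render_video(scene, protocol)
        layout = roi_geometry("mask", 10.0)
        n_body, n_roi, n_pix = len(layout.body_pixels), len(layout.roi_pixels), 64
        expected = (
            scene.background_temp * (n_pix - n_body) + scene.body_temp * n_body
        ) / n_pix + (n_roi / n_pix) * scene.breath_amp * gt.waveform.values
        assert np.allclose(tg.fvp_avg(video).values, expected, atol=1e-12)

    def test_background_only_scene_is_flat(self):
        # far enough away the breathing amplitude must be tiny relative to body
        scene = tg.SceneConfig(noise_sd=0.0, quant_step=0.0)
        video, _ = tg.render_video(scene, tg.ProtocolConfig(((10.0, 20.0),)))
        bg = video.frames[:, 0, 0]
        assert np.allclose(bg, scene.background_temp)

    def test_same_seed_bit_identical(self):
        scene = tg.SceneConfig(seed=42)
        protocol = tg.ProtocolConfig(((20.0, 20.0),))
        v1, _ = tg.render_video(scene, protocol)
        v2, _ = tg.render_video(scene, protocol)
        assert np.array_equal(v1.frames, v2.frames)

    def test_different_seed_differs(self):
        protocol = tg.ProtocolConfig(((20.0, 20.0),))
        v1, _ = tg.render_video(tg.SceneConfig(seed=1), protocol)
        v2, _ = tg.render_video(tg.SceneConfig(seed=2), protocol)
        assert not np.array_equal(v1.frames, v2.frames)

    def test_radiometric_ordering_every_frame(self):
        video, _ = tg.render_video(tg.SceneConfig(), tg.ProtocolConfig(((30.0, 20.0),)))
        layout = roi_geometry("mask", 30.0)
        body = np.zeros((8, 8), bool)
        body[layout.body_pixels[:, 0], layout.body_pixels[:, 1]] = True
        fg = video.frames[:, body].mean(axis=1)
        bg = video.frames[:, ~body].mean(axis=1)
        assert np.all(fg > bg)

    def test_parameter_recovery_noise_free(self):
        """Programmed rate and every breath peak recoverable from a clean render."""
        scene = tg.SceneConfig(noise_sd=0.0, quant_step=0.0)
        protocol = tg.ProtocolConfig(((60.0, 16.0),))
        video, gt = tg.render_video(scene, protocol)
        sig = tg.extract_signal(video, "Seg-AVG", tg.WindowPlan(length_s=10))
        trace = tg.averaged_rate(sig)
        assert np.abs(trace.rates - 16.0).max() <= 0.2
        peaks = tg.detect_peaks(sig)
        # every ground-truth peak matched within one sample (0.1 s) + half-sample slack
        for t_ref in gt.ref_peaks.peak_times:
            assert np.min(np.abs(peaks.peak_times - t_ref)) <= 0.15


class TestDatasets:
    def test_scenario_grids_have_study_sizes(self):
        assert len(dataset_a_scenarios()) == 5
        assert len(dataset_b_scenarios()) == 15
        dists = [s.distance_cm for _, s, _ in dataset_b_scenarios()]
        assert dists == list(range(10, 151, 10))

    def test_make_dataset_round_trip(self, tmp_path):
        protocol = tg.ProtocolConfig(((20.0, 20.0),))
        scenarios = [
            ("tiny-mask", tg.SceneConfig(seed=5), protocol),
            ("tiny-nostril", tg.SceneConfig(roi_kind="nostril", distance_cm=10, seed=6), protocol),
        ]
        manifest = make_dataset(scenarios, tmp_path)
        entries = load_manifest(manifest)
        assert len(entries) == 2
        for entry in entries:
            video, gt = load_scenario(entry, tmp_path)
            assert video.n_frames == 200
            assert gt.waveform.values.size == 200
            assert len(gt.ref_peaks) > 0

    def test_empty_scenario_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_dataset([], tmp_path)
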