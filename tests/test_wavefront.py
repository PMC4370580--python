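"""Onset detection, axis projection, velocities, delays, saltations."""

import numpy as np
import pytest

from vsdwave.core import AxisProfile, OnsetMap, VSDMovie
from vsdwave.preprocess import PreprocessConfig, run_chain
from vsdwave.synthetic import MAIN_AXIS
from vsdwave.wavefront import (backfill_velocity, clean_onset_map,
                               compute_threshold_map, conduction_time,
                               detect_onsets, detect_saltation,
                               estimate_velocity, peak_dff,
                               project_onto_axis, second_onset_map)

from conftest import binned_truth, detect_clean


class TestThresholdMap:
    def test_constant_baseline_gives_baseline_value(self):
        movie = VSDMovie(np.full((200, 3, 3), 7.0))
        thr = compute_threshold_map(movie, (0.0, 0.5))
        # zero variance: the degenerate epsilon is tiny for a flat movie
        assert np.allclose(thr, 7.0, atol=1e-6)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(21)
        frames = rng.normal(10.0, 2.0, size=(300, 5, 5))
        movie = VSDMovie(frames)
        thr = compute_threshold_map(movie, (0.0, 0.5))
        base = frames[:100]
        # independent two-pass oracle: explicit mean, then explicit SD
        mean = base.sum(axis=0) / 100.0
        sd = np.sqrt(((base - mean[None]) ** 2).sum(axis=0) / 100.0)
        assert np.abs(thr - (mean + 2 * sd)).max() < 1e-9

    def test_empty_baseline_window_rejected(self):
        movie = VSDMovie(np.zeros((100, 2, 2)))
        with pytest.raises(ValueError):
            compute_threshold_map(movie, (0.4, 0.4))


class TestDetectOnsets:
    def test_interpolated_step_crossing(self):
        # below threshold until frame 10, above from frame 11; the level
        # sits halfway between -> onset (10 + 0.5) / 200 = 0.0525 s
        frames = np.zeros((20, 1, 1))
        frames[11:] = 2.0
        onsets = detect_onsets(VSDMovie(frames), np.array([[1.0]]))
        assert onsets.onset_s[0, 0] == pytest.approx(0.0525)

    def test_subthreshold_pixel_is_nan(self):
        frames = np.zeros((20, 1, 2))
        frames[11:, 0, 0] = 2.0
        onsets = detect_onsets(VSDMovie(frames), np.full((1, 2), 1.0))
        assert np.isnan(onsets.onset_s[0, 1])

    def test_zero_noise_onsets_match_ground_truth(self, event_3a):
        # dF/F-branch thresholding on the native grid: detected onsets
        # within one frame interval (5 ms) of the analytic truth everywhere
        # (2x2 binning would stagger up to 4 ground-truth onsets per pixel)
        movie, truth, _ = event_3a
        cfg = PreprocessConfig(threshold_signal="dff", bin_factor=1)
        _, dff = run_chain(movie, cfg)
        thr = compute_threshold_map(dff, cfg.baseline_window_s)
        onsets = detect_onsets(dff, thr)
        gt = truth.onset.onset_s
        err = onsets.onset_s - gt
        both = np.isfinite(onsets.onset_s) & np.isfinite(gt)
        assert both.sum() > 4000
        assert np.abs(err[both]).max() < 0.005

    def test_relative_timing_preserved_on_derivative_branch(self, event_3a,
                                                            onsets_3a):
        # the symmetric differentiation window advances every crossing by a
        # common shift; relative onsets must still match the ground truth
        _, truth, _ = event_3a
        gt = binned_truth(truth)
        both = np.isfinite(onsets_3a.onset_s) & np.isfinite(gt)
        err = (onsets_3a.onset_s - gt)[both]
        assert err.std() < 0.002
        assert np.ptp(err) < 0.012

    def test_clean_onset_map_drops_isolated_pixels(self):
        onset = np.full((9, 9), np.nan)
        onset[2:6, 2:6] = 0.5          # coherent patch
        onset[8, 8] = 0.1              # isolated outlier
        cleaned = clean_onset_map(OnsetMap(onset, 0.05))
        assert np.isnan(cleaned.onset_s[8, 8])
        assert np.isfinite(cleaned.onset_s[3, 3])


class TestProjectOntoAxis:
    def test_single_pixel_hits_nearest_samples_only(self, atlas_binned):
        onset = np.full((50, 50), np.nan)
        onset[8, 20] = 0.3             # on the first band's centre row
        profile = project_onto_axis(OnsetMap(onset, 0.05), atlas_binned,
                                    MAIN_AXIS, corridor_width_mm=0.2)
        finite = np.isfinite(profile.onset_s)
        assert 1 <= finite.sum() <= 5
        d, t = profile.finite()
        assert np.allclose(t, 0.3)
        assert abs(d.mean() - 20 * 0.05) < 0.1

    def test_plane_wave_gives_linear_profile(self, atlas_binned):
        d_map = atlas_binned.axis_distance_map(MAIN_AXIS)[0]
        onset = np.where(atlas_binned.mask("CA1"), 0.1 + d_map / 370.0,
                         np.nan)
        profile = project_onto_axis(OnsetMap(onset, 0.05), atlas_binned,
                                    MAIN_AXIS)
        d, t = profile.finite()
        slope = np.polyfit(d, t, 1)[0]
        assert slope == pytest.approx(1 / 370.0, rel=0.05)

    def test_matches_brute_force_corridor_minimum(self, onsets_3a,
                                                  atlas_binned):
        profile = project_onto_axis(onsets_3a, atlas_binned, MAIN_AXIS,
                                    corridor_width_mm=0.2, step_mm=0.1)
        dists, pts = atlas_binned.axis_paths[MAIN_AXIS].sample(0.1)
        h, w = onsets_3a.shape
        rr, cc = np.mgrid[0:h, 0:w]
        px = np.column_stack([cc.ravel() * 0.05, rr.ravel() * 0.05])
        vals = onsets_3a.onset_s.ravel()
        for j in range(0, len(dists), 7):
            dist2 = ((px - pts[j]) ** 2).sum(axis=1)
            captured = vals[dist2 <= 0.1 ** 2]
            captured = captured[np.isfinite(captured)]
            expected = captured.min() if captured.size else np.nan
            got = profile.onset_s[j]
            assert (np.isnan(got) and np.isnan(expected)) or \
                got == pytest.approx(expected)


class TestEstimateVelocity:
    def test_exact_profiles_recover_preset_velocities(self):
        d = np.linspace(0.6, 1.8, 25)
        for v in (0.37, 0.17):
            profile = AxisProfile("x", d, d / (1000 * v), 0.2)
            fit = estimate_velocity(profile)
            assert fit.velocity_m_s == pytest.approx(v, rel=1e-6)

    def test_too_few_samples_rejected(self):
        profile = AxisProfile("x", np.array([0.0, 0.1, 0.2]),
                              np.array([0.0, 0.1, 0.2]), 0.2)
        with pytest.raises(ValueError, match="4"):
            estimate_velocity(profile)

    def test_flat_profile_flags_infinite(self):
        profile = AxisProfile("x", np.linspace(0, 1, 10),
                              np.full(10, 0.5), 0.2)
        fit = estimate_velocity(profile)
        assert fit.infinite and np.isinf(fit.velocity_m_s)

    def test_single_outlier_moves_fit_less_than_ten_percent(self):
        d = np.linspace(0.0, 2.0, 20)
        t = d / 370.0
        t_out = t.copy()
        t_out[7] += 0.25               # grossly late outlier
        clean = estimate_velocity(AxisProfile("x", d, t, 0.2))
        dirty = estimate_velocity(AxisProfile("x", d, t_out, 0.2))
        change = abs(dirty.velocity_m_s - clean.velocity_m_s)
        assert change < 0.1 * abs(clean.velocity_m_s)


class TestConductionTime:
    def test_preset_25ms_delay_recovered(self, onsets_3a, atlas_binned):
        delay = conduction_time(onsets_3a, atlas_binned, "CA1", "Au1_L56")
        assert delay == pytest.approx(25.0, abs=5.0)

    def test_same_region_is_zero(self, onsets_3a, atlas_binned):
        assert conduction_time(onsets_3a, atlas_binned, "CA1", "CA1") == 0.0

    def test_return_path_74ms_on_second_onsets(self, event_3b, atlas_binned):
        movie, _, _ = event_3b
        cfg = PreprocessConfig()
        filtered, dff = run_chain(movie, cfg)
        thr = compute_threshold_map(filtered, cfg.baseline_window_s)
        first = detect_onsets(filtered, thr, validation_movie=dff,
                              validation_threshold_map=compute_threshold_map(
                                  dff, cfg.baseline_window_s))
        second = second_onset_map(filtered, thr, first)
        delay = conduction_time(second, atlas_binned, "Au1_L56", "CA1")
        assert delay == pytest.approx(74.0, abs=5.0)

    def test_region_without_onsets_named_in_error(self, event_1, atlas_binned):
        movie, _, _ = event_1
        onsets = detect_clean(movie)
        with pytest.raises(ValueError, match="mEC"):
            conduction_time(onsets, atlas_binned, "CA1", "mEC")


class TestDetectSaltation:
    def test_monotonic_profile_has_no_saltations(self):
        d = np.linspace(0, 5, 60)
        profile = AxisProfile("x", d, 0.1 + d / 100.0, 0.2)
        assert detect_saltation(profile) == []

    def test_two_generated_jumps_recovered(self, onsets_3a, atlas_binned,
                                           event_3a):
        _, _, spec = event_3a
        profile = project_onto_axis(onsets_3a, atlas_binned, MAIN_AXIS)
        keep = (profile.distance_mm >= 2.6) & (profile.distance_mm <= 5.8)
        periallo = AxisProfile(MAIN_AXIS, profile.distance_mm[keep],
                               profile.onset_s[keep],
                               profile.corridor_width_mm)
        salts = detect_saltation(periallo)
        assert len(salts) == 2
        for salt, jump in zip(salts, spec.jump_list):
            assert salt.jump_to_mm == pytest.approx(jump.to_mm, abs=0.15)
            assert salt.jump_from_mm == pytest.approx(jump.from_mm, abs=0.15)

    def test_backfill_velocity_recovered_on_clean_limb(self, onsets_3a,
                                                       atlas_binned):
        profile = project_onto_axis(onsets_3a, atlas_binned, MAIN_AXIS)
        keep = (profile.distance_mm >= 2.6) & (profile.distance_mm <= 5.8)
        periallo = AxisProfile(MAIN_AXIS, profile.distance_mm[keep],
                               profile.onset_s[keep],
                               profile.corridor_width_mm)
        for salt in detect_saltation(periallo):
            assert salt.backfill_velocity_m_s == pytest.approx(0.47,
                                                               abs=0.11)

    def test_regional_population_fit_matches_preset(self, onsets_3a,
                                                    atlas_binned):
        fits = backfill_velocity(onsets_3a, atlas_binned)
        assert set(fits) == {"mEC", "lEC"}
        for v in fits.values():
            assert v == pytest.approx(0.47, abs=0.11)


class TestPeakDff:
    def test_zero_region_gives_zero(self, atlas_binned):
        movie = VSDMovie(np.zeros((100, 50, 50)), pixel_pitch_mm=0.05)
        assert peak_dff(movie, atlas_binned, "CA1") == 0.0

    def test_generator_amplitude_recovered(self, event_3a, atlas_binned):
        movie, _, spec = event_3a
        cfg = PreprocessConfig()
        _, dff = run_chain(movie, cfg)
        got = peak_dff(dff, atlas_binned, "CA1")
        assert got == pytest.approx(spec.peak_dff["CA1"], rel=0.05)

    def test_matches_brute_force_region_mean_trace(self, event_3a,
                                                   atlas_binned):
        movie, _, _ = event_3a
        _, dff = run_chain(movie, PreprocessConfig())
        mask = atlas_binned.mask("CA3")
        trace = np.array([frame[mask].mean() for frame in dff.frames])
        assert peak_dff(dff, atlas_binned, "CA3") == pytest.approx(
            trace.max())
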