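"""Generator contracts: atlas geometry, event kinematics, noise, cohorts, LFP."""

import numpy as np
import pytest

from vsdwave.core import HIPPOCAMPAL_REGIONS
from vsdwave.synthetic import (MAIN_AXIS, CohortSpec, EventSpec,
                               LFPShapeParams, add_noise_and_bleach,
                               build_region_atlas, default_geometry,
                               iter_cohort, make_event_spec, simulate_cohort,
                               simulate_event, simulate_lfp,
                               simulate_lfp_pair, _dmap)
from vsdwave.lfp import bandpass, classify_morphology


class TestBuildRegionAtlas:
    def test_default_atlas_has_eight_regions_and_long_axis(self, atlas):
        assert sorted(atlas.name_to_label) == [
            "Au1_L23", "Au1_L56", "CA1", "CA3", "lEC", "mEC",
            "perirhinal", "subiculum"]
        assert atlas.axis_paths[MAIN_AXIS].length_mm >= 5.0
        # every region is non-empty
        for name in atlas.name_to_label:
            assert atlas.mask(name).any()

    def test_overlapping_polygons_rejected(self):
        cfg = default_geometry()
        cfg["regions"][1]["polygon"] = cfg["regions"][0]["polygon"]
        with pytest.raises(ValueError, match="overlap"):
            build_region_atlas(cfg)

    def test_axis_leaving_grid_rejected(self):
        cfg = default_geometry()
        cfg["axes"]["bad"] = [(0, 0), (0, 150)]
        with pytest.raises(ValueError, match="grid"):
            build_region_atlas(cfg)


class TestEventSpec:
    def test_reverb_latency_present_iff_3b(self, atlas):
        spec = make_event_spec("3b", atlas, reverb_latency_s=0.6)
        assert spec.reverb_latency_s == 0.6
        with pytest.raises(ValueError, match="iff"):
            EventSpec("3a", "CA1", (0, 0), spec.segment_kinematics,
                      reverb_latency_s=0.5)

    def test_reverb_latency_window_enforced(self, atlas):
        with pytest.raises(ValueError, match="window"):
            make_event_spec("3b", atlas, reverb_latency_s=1.5)

    def test_event_duration_bounds(self, atlas):
        spec = make_event_spec("1", atlas)
        assert 0.2 <= spec.event_duration_s <= 2.8
        with pytest.raises(ValueError, match="duration"):
            EventSpec("1", "CA1", (0, 0), spec.segment_kinematics,
                      event_duration_s=3.5)

    def test_all_velocities_positive(self, atlas):
        for etype in ("1", "2", "3a", "other"):
            spec = make_event_spec(etype, atlas)
            assert all(b.velocity_m_s > 0 for b in spec.segment_kinematics)


class TestSimulateEvent:
    def test_type1_confined_to_hippocampus(self, event_1, atlas):
        _, truth, _ = event_1
        fin = np.isfinite(truth.onset.onset_s)
        outside = ~atlas.mask_any(HIPPOCAMPAL_REGIONS)
        assert not fin[outside].any()
        assert fin[atlas.mask("CA1")].any() and fin[atlas.mask("CA3")].any()

    def test_zero_noise_onsets_follow_distance_over_velocity(self, atlas):
        # single-branch event: onset must equal t0 + |d - d0| / v exactly
        spec = make_event_spec("1", atlas)
        _, truth, = simulate_event(spec, atlas)[:2]
        d = _dmap(atlas, MAIN_AXIS)
        ca1_branch = [b for b in spec.segment_kinematics
                      if b.regions == frozenset({"CA1"})][0]
        m = atlas.mask("CA1") & np.isfinite(truth.onset.onset_s)
        expected = spec.origin_time_s + ca1_branch.t0_s + np.abs(
            d[m] - ca1_branch.d0_mm) / (1000.0 * ca1_branch.velocity_m_s)
        assert np.allclose(truth.onset.onset_s[m], expected, atol=1e-12)

    def test_3b_second_hippocampal_onset_at_latency(self, event_3b, atlas):
        _, truth, spec = event_3b
        hip = atlas.mask_any(HIPPOCAMPAL_REGIONS)
        au1_first = np.nanmin(truth.onset.onset_s[atlas.mask("Au1_L56")])
        second = truth.second_onset_s[hip]
        assert np.isfinite(second).any()
        earliest_second = np.nanmin(second)
        assert earliest_second - au1_first == pytest.approx(0.6, abs=1e-9)

    def test_missing_region_rejected(self, atlas):
        spec = make_event_spec("1", atlas)
        spec.peak_dff = {**spec.peak_dff, "thalamus": 0.1}
        with pytest.raises(ValueError, match="thalamus"):
            simulate_event(spec, atlas)

    def test_amplitude_scaled_per_region(self, event_3a, atlas):
        movie, _, spec = event_3a
        f0 = spec.f0_counts
        ca1_peak = movie.frames[:, atlas.mask("CA1")].max()
        expected = f0 * (1 + spec.peak_dff["CA1"] / 100.0)
        assert ca1_peak == pytest.approx(expected, rel=1e-4)


class TestNoiseAndBleach:
    def test_zero_noise_zero_bleach_is_identity(self, event_1):
        movie, _, _ = event_1
        out = add_noise_and_bleach(movie, noise_sd=0.0, bleach_rate=0.0)
        assert np.array_equal(out.frames, movie.frames)

    def test_bleach_follows_exponential_decay(self):
        from vsdwave.core import VSDMovie
        movie = VSDMovie(np.full((400, 4, 4), 1000.0), frame_rate=200.0)
        out = add_noise_and_bleach(movie, noise_sd=0.0, bleach_rate=0.05,
                                  seed=0)
        expected = 1000.0 * np.exp(-0.05 * movie.times)
        assert np.allclose(out.frames.mean(axis=(1, 2)), expected, rtol=1e-6)

    def test_fixed_seed_is_bit_identical(self, event_1):
        movie, _, _ = event_1
        a = add_noise_and_bleach(movie, seed=9)
        b = add_noise_and_bleach(movie, seed=9)
        assert np.array_equal(a.frames, b.frames)
        c = add_noise_and_bleach(movie, seed=10)
        assert not np.array_equal(a.frames, c.frames)


class TestCohort:
    def test_default_composition_is_57_events(self, atlas):
        cohort = CohortSpec()
        assert cohort.total == 57
        types = [e.spec.event_type
                 for e in iter_cohort(CohortSpec(noise_sd=0.0,
                                                 bleach_rate=0.0), atlas)]
        assert types.count("1") == 14
        assert types.count("2") == 11
        assert types.count("3a") == 23
        assert types.count("3b") == 7
        assert types.count("other") == 2

    def test_all_counts_zero_gives_empty_list(self, atlas):
        cohort = CohortSpec(n_type1=0, n_type2=0, n_type3a=0, n_type3b=0,
                            n_other=0)
        assert simulate_cohort(cohort, atlas) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_type1=-1)

    def test_same_master_seed_reproduces_cohort(self, atlas):
        spec = CohortSpec(n_type1=1, n_type2=0, n_type3a=1, n_type3b=1,
                          n_other=0, master_seed=5)
        a = simulate_cohort(spec, atlas)
        b = simulate_cohort(spec, atlas)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.movie.frames, eb.movie.frames)
            assert ea.spec.reverb_latency_s == eb.spec.reverb_latency_s


class TestSimulateLFP:
    @pytest.mark.parametrize("morph,n_expected,polarity", [
        ("biphasic", 2, "negative"),
        ("triphasic", 4, "positive"),
    ])
    def test_default_morphologies(self, morph, n_expected, polarity):
        p = LFPShapeParams(morphology=morph)
        res = classify_morphology(bandpass(simulate_lfp(morph, seed=1)),
                                  p.event_window_s)
        assert res.n_crossings == n_expected
        assert res.morphology == morph
        assert res.initial_polarity == polarity

    def test_zero_amplitude_gives_flat_trace(self):
        p = LFPShapeParams("biphasic", p2p_uV=0.0, noise_sd_uV=0.0)
        trace = simulate_lfp("biphasic", p, seed=1)
        assert np.allclose(trace.samples_uV, 0.0)

    def test_sample_rate_is_2khz(self):
        assert simulate_lfp("biphasic", seed=1).sample_rate == 2000.0

    def test_pair_presets_channel_order(self):
        a, b = simulate_lfp_pair("type2", seed=3)
        assert (a.channel_label, b.channel_label) == ("L2/3", "L5/6")
        a, b = simulate_lfp_pair("type3", seed=3)
        assert (a.channel_label, b.channel_label) == ("L5/6", "L2/3")
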