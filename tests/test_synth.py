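"""Synthetic movie generator: atlas geometry, noise model, event
injection, ground-truth bookkeeping, cohort and stimulation sessions."""

import numpy as np
import pytest

from vasowave.core import AcquisitionSpec, Movie
from vasowave.atlas import build_atlas, REGION_NAMES
from vasowave.patterns import PatternLabel
from vasowave.preproc import roi_timecourses
from vasowave.spectral import amplitude_spectrum
from vasowave import synth
from vasowave.synth import (
    GroundTruthLog,
    NoiseSpec,
    StimulusProtocol,
    WaveSpec,
    inject_static_event,
    inject_travelling_wave,
    simulate_baseline,
    simulate_cohort,
    simulate_stim_session,
)


class TestAtlas:
    def test_contains_all_named_regions_with_usable_footprints(self, atlas64):
        names = set(atlas64.names.values())
        assert names == set(REGION_NAMES)
        for rid in atlas64.all_ids():
            assert np.count_nonzero(atlas64.labels == rid) >= 15

    def test_hemispheres_mirror_about_midline(self, atlas64):
        lab = atlas64.labels
        swapped = np.zeros_like(lab)
        for i, name in atlas64.names.items():
            other = "left" if atlas64.hemisphere[i] == "right" else "right"
            swapped[lab == i] = atlas64.id_of(name, other)
        assert np.array_equal(lab[:, ::-1], swapped)

    def test_every_pixel_is_background_or_a_known_id(self, atlas64):
        assert set(np.unique(atlas64.labels)) <= {0} | set(atlas64.names)

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            build_atlas(AcquisitionSpec(32, 32, 100))

    def test_cortex_ordered_medial_to_temporal(self, atlas64):
        mid = atlas64.midline_col
        dists = []
        for name in ("RetroGrCtx_B", "RetroGrCtx_A", "RetroDysCtx", "SecVisCtx", "PrimVisCtx"):
            cols = np.nonzero(atlas64.mask(name, "right"))[1]
            dists.append(np.abs(cols - mid).mean())
        assert dists == sorted(dists)


class TestBaseline:
    def test_zero_noise_gives_constant_pixel_series(self, atlas64, spec64_short):
        m = simulate_baseline(atlas64, spec64_short, NoiseSpec(0, 0), seed=0)
        assert np.all(m.data == m.data[:, :, :1])
        assert np.all(m.data > 0)

    def test_white_noise_sd_calibrated_at_long_records(self, atlas64):
        spec = AcquisitionSpec(64, 64, 3000)
        s = 2.0
        m = simulate_baseline(atlas64, spec, NoiseSpec(white_sd=s, pink_sd=0), seed=3)
        rows, cols = np.unravel_index(
            np.random.default_rng(0).choice(64 * 64, 100, replace=False), (64, 64)
        )
        sds = m.data[rows, cols, :].std(axis=1)
        assert abs(sds.mean() - s) / s < 0.05

    def test_identical_seed_is_bit_identical(self, atlas64, spec64_short):
        a = simulate_baseline(atlas64, spec64_short, NoiseSpec(), seed=7)
        b = simulate_baseline(atlas64, spec64_short, NoiseSpec(), seed=7)
        assert np.array_equal(a.data, b.data)

    def test_nonfinite_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=np.nan)
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=-1.0)

    def test_pink_noise_spectrum_falls_with_frequency(self, atlas64, spec64_short):
        m = simulate_baseline(
            atlas64, spec64_short, NoiseSpec(white_sd=0, pink_sd=1.0), seed=5
        )
        spec = amplitude_spectrum(m.data[30, 30, :].astype(float), 0.4)
        lo = spec.amplitude[(spec.freqs > 0.01) & (spec.freqs < 0.05)].mean()
        hi = spec.amplitude[(spec.freqs > 0.5) & (spec.freqs < 1.0)].mean()
        assert lo > 3 * hi


class TestWaveInjection:
    def test_unit_conversion_quarter_mm_s_is_one_px_per_frame(
        self, atlas64, quiet_baseline
    ):
        # 0.25 mm/s on a 0.1 mm / 0.4 s grid -> 1 px per frame
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        wave = WaveSpec(path=((30.0, 10.0), (30.0, 40.0)), speed=0.25, freq=0.1,
                        amplitude_pct=10, t_onset=50)
        inject_travelling_wave(m, atlas64, wave, gt)
        track = gt.events[0].centroid_track
        steps = [track[i + 1][2] - track[i][2] for i in range(len(track) - 1)]
        assert np.allclose(steps, 1.0)

    def test_peak_relative_amplitude_matches_injection(self, atlas64, quiet_baseline):
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        wave = WaveSpec(path=((30.0, 20.0), (30.0, 30.0)), speed=0.25, freq=0.1,
                        amplitude_pct=20, t_onset=50)
        inject_travelling_wave(m, atlas64, wave, gt)
        rel = m.data / quiet_baseline.data - 1.0
        assert abs(rel.max() - 0.20) < 0.01

    def test_disjoint_onsets_give_time_shifted_copies(self, atlas64, quiet_baseline):
        kw = dict(path=((30.0, 20.0), (30.0, 30.0)), speed=0.25, freq=0.1,
                  amplitude_pct=15)
        m = quiet_baseline.copy()
        gt = GroundTruthLog()
        inject_travelling_wave(m, atlas64, WaveSpec(t_onset=100, **kw), gt)
        inject_travelling_wave(m, atlas64, WaveSpec(t_onset=400, **kw), gt)
        diff = m.data - quiet_baseline.data
        assert np.allclose(diff[:, :, 100:130], diff[:, :, 400:430], atol=1e-5)

    def test_energy_outside_three_sigma_is_exactly_baseline(
        self, atlas64, quiet_baseline
    ):
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        wave = WaveSpec(path=((30.0, 25.0),), speed=0.25, freq=0.1,
                        amplitude_pct=30, width_mm=0.5, t_onset=50)
        inject_travelling_wave(m, atlas64, wave, gt)
        sigma_px = 0.5 / 0.1
        rr, cc = np.mgrid[0:64, 0:64]
        outside = (rr - 30.0) ** 2 + (cc - 25.0) ** 2 > (3 * sigma_px) ** 2
        assert np.array_equal(m.data[outside, :], quiet_baseline.data[outside, :])

    def test_ground_truth_path_length_matches_track(self, atlas64, quiet_baseline):
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        wave = WaveSpec(path=((20.0, 10.0), (25.0, 30.0), (30.0, 31.0)), speed=0.4,
                        freq=0.1, amplitude_pct=10, t_onset=50)
        inject_travelling_wave(m, atlas64, wave, gt)
        track = np.array([(r, c) for _, r, c in gt.events[0].centroid_track])
        recomputed = np.sum(np.linalg.norm(np.diff(track, axis=0), axis=1))
        assert abs(gt.events[0].path_length_px - recomputed) < 1e-9

    def test_invalid_wave_parameters_rejected(self):
        with pytest.raises(ValueError):
            WaveSpec(path=((1.0, 1.0),), speed=0, freq=0.1, amplitude_pct=5)
        with pytest.raises(ValueError):
            WaveSpec(path=((1.0, 1.0),), speed=0.2, freq=-1, amplitude_pct=5)

    def test_wave_outside_image_or_record_rejected(self, atlas64, quiet_baseline):
        gt = GroundTruthLog()
        with pytest.raises(ValueError, match="inside the image"):
            inject_travelling_wave(
                quiet_baseline.copy(), atlas64,
                WaveSpec(path=((200.0, 10.0),), speed=0.2, freq=0.1, amplitude_pct=5),
                gt,
            )
        with pytest.raises(ValueError, match="does not fit"):
            inject_travelling_wave(
                quiet_baseline.copy(), atlas64,
                WaveSpec(path=((30.0, 30.0),), speed=0.2, freq=0.1,
                         amplitude_pct=5, t_onset=740),
                gt,
            )

    def test_noise_free_train_spectrum_peaks_at_carrier(self, atlas64, spec64):
        m = simulate_baseline(atlas64, spec64, NoiseSpec(0, 0), seed=0)
        gt = GroundTruthLog()
        f = 0.125
        centre = tuple(np.array(np.nonzero(atlas64.mask("PrimVisCtx", "right"))).mean(axis=1))
        # train spanning the record: the nonnegative carrier's envelope is
        # then a constant offset, which the DC-excluded spectrum drops
        n_cycles = int(f * spec64.duration_s) - 1
        wave = WaveSpec(path=(centre,), speed=0.2, freq=f, amplitude_pct=20,
                        width_mm=1.2, t_onset=4, n_cycles=n_cycles)
        inject_travelling_wave(m, atlas64, wave, gt)
        rid = atlas64.id_of("PrimVisCtx", "right")
        series = roi_timecourses(m, atlas64, [rid]).series[rid]
        spec = amplitude_spectrum(series, 0.4)
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(spec.peak_freq() - f) <= df


class TestStaticEvents:
    def test_static_event_has_zero_path_length(self, atlas64, quiet_baseline):
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        inject_static_event(m, atlas64, (30.0, 25.0), amplitude_pct=15,
                            duration_frames=10, width_mm=0.5, t_onset=100,
                            ground_truth=gt)
        ev = gt.events[0]
        assert ev.path_length_px == 0.0
        assert ev.dynamic is False

    def test_series_returns_to_baseline_after_event(self, atlas64, quiet_baseline):
        gt = GroundTruthLog()
        m = quiet_baseline.copy()
        inject_static_event(m, atlas64, (30.0, 25.0), amplitude_pct=15,
                            duration_frames=10, width_mm=0.5, t_onset=100,
                            ground_truth=gt)
        centre_series = m.data[30, 25, :]
        base = quiet_baseline.data[30, 25, :]
        assert np.array_equal(centre_series[:100], base[:100])
        assert np.array_equal(centre_series[112:], base[112:])
        assert centre_series[100:110].max() > base[0]

    def test_overlapping_events_compose_multiplicatively(self, atlas64, quiet_baseline):
        g1, g2, g3 = GroundTruthLog(), GroundTruthLog(), GroundTruthLog()
        kw = dict(amplitude_pct=10, duration_frames=10, width_mm=0.5, t_onset=100)
        a = quiet_baseline.copy()
        inject_static_event(a, atlas64, (30.0, 25.0), ground_truth=g1, **kw)
        b = quiet_baseline.copy()
        inject_static_event(b, atlas64, (31.0, 26.0), ground_truth=g2, **kw)
        both = quiet_baseline.copy()
        inject_static_event(both, atlas64, (30.0, 25.0), ground_truth=g3, **kw)
        inject_static_event(both, atlas64, (31.0, 26.0), ground_truth=g3, **kw)
        expected = a.data / quiet_baseline.data * b.data / quiet_baseline.data
        assert np.allclose(both.data / quiet_baseline.data, expected, atol=1e-5)


class TestCohort:
    def test_lps_arm_higher_amplitude_than_veh_by_construction(self, spec64, atlas64):
        veh = simulate_cohort("VEH", 2, spec64, seed=0, atlas=atlas64)
        lps = simulate_cohort("LPS", 2, spec64, seed=0, atlas=atlas64)
        amp = lambda scans: np.mean(
            [e.amplitude_pct for _, g in scans for e in g.events]
        )
        assert amp(lps) > amp(veh)

    def test_scans_share_statistics_but_differ_in_timing(self, spec64, atlas64):
        scans = simulate_cohort("VEH", 2, spec64, seed=5, atlas=atlas64)
        (m0, g0), (m1, g1) = scans
        assert not np.array_equal(m0.data, m1.data)

    def test_unknown_arm_rejected(self, spec64, atlas64):
        with pytest.raises(ValueError, match="unknown arm"):
            simulate_cohort("SALINE", 1, spec64, seed=0, atlas=atlas64)

    def test_event_counts_scale_with_rate(self, spec64, atlas64):
        # Poisson(rate x duration): 20 scans at 0.3/min over 10 min
        scans = simulate_cohort("VEH", 20, spec64, seed=9, atlas=atlas64,
                                noise=synth.NoiseSpec(0.0, 0.0))
        n_waves = [len(g.of_kind("wave")) for _, g in scans]
        expected = 0.3 * spec64.duration_s / 60.0
        se = np.sqrt(expected / len(scans))
        assert abs(np.mean(n_waves) - expected) < 4 * se


class TestStimSession:
    def test_four_blocks_give_four_disjoint_epochs_zero_noise(self, atlas64):
        spec = AcquisitionSpec(64, 64, 900)
        protocol = StimulusProtocol()
        movie, gt = simulate_stim_session(
            atlas64, spec, protocol,
            {"regions": ["PrimVisCtx"], "amplitude_pct": 10, "rise_s": 0, "fall_s": 0},
            noise=NoiseSpec(0, 0),
        )
        rid = atlas64.id_of("PrimVisCtx", "right")
        series = roi_timecourses(movie, atlas64, [rid]).series[rid]
        above = series > series.min() * 1.001
        transitions = np.diff(above.astype(int))
        assert (transitions == 1).sum() == 4
        assert len(gt.of_kind("stim")) == 4

    def test_non_target_roi_untouched_in_zero_noise_run(self, atlas64):
        spec = AcquisitionSpec(64, 64, 900)
        movie, _ = simulate_stim_session(
            atlas64, spec, StimulusProtocol(),
            {"regions": ["PrimVisCtx"], "amplitude_pct": 10, "rise_s": 0, "fall_s": 0},
            noise=NoiseSpec(0, 0),
        )
        rid = atlas64.id_of("Hippocampus", "left")
        series = roi_timecourses(movie, atlas64, [rid]).series[rid]
        assert np.ptp(series) < 1e-6

    def test_slow_rise_lowers_block_mean_toward_plateau(self, atlas64):
        spec = AcquisitionSpec(64, 64, 900)
        protocol = StimulusProtocol()
        means = {}
        for rise in (8.0, 0.0):
            movie, _ = simulate_stim_session(
                atlas64, spec, protocol,
                {"regions": ["PrimVisCtx"], "amplitude_pct": 10,
                 "rise_s": rise, "fall_s": 1.0},
                noise=NoiseSpec(0, 0),
            )
            rid = atlas64.id_of("PrimVisCtx", "right")
            series = roi_timecourses(movie, atlas64, [rid]).series[rid]
            base = series[: int(30 / 0.4)].mean()
            rel = 100 * (series / base - 1)
            s, e = protocol.stim_epochs(0.4)[0]
            means[rise] = rel[s:e].mean()
        assert means[8.0] < means[0.0] <= 10.0 + 1e-6
        assert means[0.0] > 9.99

    def test_unknown_region_and_overlong_protocol_rejected(self, atlas64):
        spec = AcquisitionSpec(64, 64, 900)
        with pytest.raises(ValueError, match="not in atlas"):
            simulate_stim_session(
                atlas64, spec, StimulusProtocol(),
                {"regions": [999], "amplitude_pct": 10},
            )
        with pytest.raises(ValueError, match="exceeds"):
            simulate_stim_session(
                atlas64, AcquisitionSpec(64, 64, 100), StimulusProtocol(),
                {"regions": ["PrimVisCtx"], "amplitude_pct": 10},
            )


def test_ground_truth_log_json_roundtrip(tmp_path, atlas64, quiet_baseline):
    gt = GroundTruthLog(seed=3)
    m = quiet_baseline.copy()
    wave = WaveSpec(path=((30.0, 10.0), (30.0, 40.0)), speed=0.25, freq=0.1,
                    amplitude_pct=10, t_onset=50, pattern=PatternLabel.MEDIO_TEMPORAL)
    inject_travelling_wave(m, atlas64, wave, gt)
    path = tmp_path / "gt.json"
    gt.to_json(path)
    back = GroundTruthLog.from_json(path)
    assert back.seed == 3
    assert back.events[0].pattern == "MEDIO_TEMPORAL"
    assert back.events[0].path_length_px == gt.events[0].path_length_px
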