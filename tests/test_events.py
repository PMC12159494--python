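"""Event detector: robust z-scoring, connected-component extraction
against a brute-force flood-fill oracle, feature computation, and
dynamic/static classification."""

from collections import deque

import numpy as np
import pytest

from vasowave.core import AcquisitionSpec, Movie
from vasowave.events import (
    DetectorConfig,
    EventRecord,
    classify_dynamic,
    detect_events,
    event_features,
    robust_zscore,
    smooth_z,
    summarize_scan,
    train_speed,
)


def _movie(data, dt=0.4):
    data = np.asarray(data, dtype=np.float32)
    return Movie(data, AcquisitionSpec(*data.shape, dt=dt))


class TestRobustZscore:
    def test_white_noise_z_is_approximately_standard_normal(self, rng):
        data = rng.standard_normal((8, 8, 3000)).astype(np.float32) * 2.0
        m = _movie(data + 50)
        z, sd = robust_zscore(m)
        centred = (m.data - np.median(m.data, axis=2, keepdims=True)) / sd[:, :, None]
        assert abs(centred.std() - 1.0) < 0.1
        assert abs(sd.mean() - 2.0) / 2.0 < 0.1

    def test_slow_wave_barely_inflates_difference_based_sd(self, rng):
        # a 0.1 Hz sinusoid at 2.5x the noise sd moves first differences
        # by only ~2 sin(pi f dt) of its amplitude: < 10% sd inflation,
        # where the plain sd would nearly double
        n = 3000
        t = np.arange(n) * 0.4
        noise = rng.standard_normal((4, 4, n)).astype(np.float32)
        m_plain = _movie(noise + 50)
        wave = 2.5 * np.sin(2 * np.pi * 0.1 * t)
        m_wavy = _movie(noise + 50 + wave.astype(np.float32))
        _, sd_plain = robust_zscore(m_plain)
        _, sd_wavy = robust_zscore(m_wavy)
        assert np.all(sd_wavy / sd_plain < 1.1)
        naive_inflation = m_wavy.data[0, 0].std() / m_plain.data[0, 0].std()
        assert naive_inflation > 1.5

    def test_scale_invariance_of_z(self, rng):
        data = rng.standard_normal((4, 4, 500)).astype(np.float32) + 20
        z1, _ = robust_zscore(_movie(data))
        z2, _ = robust_zscore(_movie(2.0 * data))
        assert np.allclose(z1, z2, rtol=1e-4)

    def test_zero_variance_pixel_floored_with_warning(self):
        data = np.ones((4, 4, 100), dtype=np.float32)
        with pytest.warns(RuntimeWarning, match="floored"):
            z, sd = robust_zscore(_movie(data))
        assert np.all(np.isfinite(z))


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Brute-force oracle: BFS over 8-neighbour spatial + same-pixel
    temporal adjacency."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    h, w, n = mask.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            r, c, t = q.popleft()
            comp.add((r, c, t))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc, t] and not seen[rr, cc, t]:
                        seen[rr, cc, t] = True
                        q.append((rr, cc, t))
            for dt in (-1, 1):
                tt = t + dt
                if 0 <= tt < n and mask[r, c, tt] and not seen[r, c, tt]:
                    seen[r, c, tt] = True
                    q.append((r, c, tt))
        comps.append(comp)
    return comps


class TestDetectOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_flood_fill_oracle(self, seed):
        """Detector components equal brute-force flood fill exactly."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((24, 24, 60)).astype(np.float32)
        # plant a few blobs so some components clear the size gate
        for _ in range(4):
            r, c, t = rng.integers(4, 20), rng.integers(4, 20), rng.integers(5, 50)
            z[r - 3 : r + 4, c - 3 : c + 4, t : t + 6] += 40.0
        config = DetectorConfig(smoothing_sigma_px=0.5, min_size_px=15,
                                split_events=False)
        z_s = smooth_z(z, config)
        events = detect_events(z, config)
        mask = z_s > config.z_threshold
        oracle = [
            comp for comp in flood_fill_components(mask)
            if max(
                sum(1 for (r, c, t) in comp if t == tt)
                for tt in {t for _, _, t in comp}
            ) >= config.min_size_px
        ]
        detected = [
            {(r, c, t) for t, fp in ev.footprints.items() for r, c in map(tuple, fp)}
            for ev in events
        ]
        assert sorted(map(sorted, detected)) == sorted(map(sorted, oracle))

    def test_lower_threshold_never_reduces_event_count(self, rng):
        z = rng.standard_normal((24, 24, 60)).astype(np.float32)
        for t0 in (10, 30, 50):
            z[8:14, 8:14, t0 : t0 + 4] += 30.0
        n_hi = len(detect_events(z, DetectorConfig(z_threshold=8, split_events=False)))
        n_lo = len(detect_events(z, DetectorConfig(z_threshold=4, split_events=False)))
        assert n_lo >= n_hi

    def test_pure_noise_produces_no_events(self, rng):
        z = rng.standard_normal((32, 32, 200)).astype(np.float32)
        assert detect_events(z) == []

    def test_two_temporally_disjoint_blobs_give_two_events(self, rng):
        z = rng.standard_normal((24, 24, 80)).astype(np.float32) * 0.1
        z[6:12, 6:12, 10:16] += 30.0
        z[14:20, 14:20, 50:56] += 30.0
        events = detect_events(z)
        assert len(events) == 2
        assert events[0].t_start <= 11 and events[0].t_end >= 14
        assert events[1].t_start <= 51 and events[1].t_end >= 54

    def test_saddle_separated_peaks_are_split(self):
        rr = np.arange(40)[:, None, None]
        # two Gaussian ridges joined by a supra-threshold bridge
        def ridges(bridge):
            prof = (20 * np.exp(-((rr - 12.0) ** 2) / 8)
                    + 20 * np.exp(-((rr - 28.0) ** 2) / 8))
            prof = np.maximum(prof, bridge)
            z = np.zeros((40, 20, 30), dtype=np.float32)
            z[:, 4:16, 8:20] = prof
            return z

        weak = ridges(bridge=7.0)  # saddle < 50% of the peaks
        assert len(detect_events(weak, DetectorConfig(split_events=False))) == 1
        assert len(detect_events(weak, DetectorConfig(split_events=True))) == 2
        strong = ridges(bridge=14.0)  # saddle above 50%: stays one event
        assert len(detect_events(strong, DetectorConfig(split_events=True))) == 1


def _record_from_track(track, width=3):
    """EventRecord whose per-frame footprints are small squares centred
    on the given track (uniform z -> centroid = square centre)."""
    footprints = {}
    for t, (r, c) in enumerate(track):
        rr, cc = np.mgrid[r - 1 : r + 2, c - 1 : c + 2]
        footprints[t] = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.int32)
    return EventRecord(
        event_id=0, t_start=0, t_end=len(track) - 1,
        footprints=footprints, seed=(track[0][0], track[0][1], 0), peak_z=10.0,
    )


class TestFeatures:
    def _complete(self, record, n_frames=10, shape=(32, 32)):
        spec = AcquisitionSpec(*shape, n_frames)
        z = np.ones((*shape, n_frames), dtype=np.float32)
        pct = Movie(np.zeros((*shape, n_frames), dtype=np.float32) + 1, spec)
        return event_features(record, pct, z, spec)

    def test_straight_track_propagation_is_displacement_sum(self):
        ev = self._complete(_record_from_track([(10, 10), (10, 13), (10, 16)]))
        assert ev.propagation_px == pytest.approx(6.0)
        assert classify_dynamic(ev) is True  # 6 px > 5 px rule

    def test_short_track_stays_static(self):
        ev = self._complete(_record_from_track([(10, 10), (10, 12), (10, 14)]))
        assert ev.propagation_px == pytest.approx(4.0)
        assert classify_dynamic(ev) is False

    def test_propagation_matches_independent_recomputation(self, rng):
        track = [(10 + i, 10 + int(rng.integers(0, 3))) for i in range(8)]
        ev = self._complete(_record_from_track(track))
        recomputed = float(
            np.sum(np.linalg.norm(np.diff(ev.centroid_track, axis=0), axis=1))
        )
        assert abs(ev.propagation_px - recomputed) < 1e-9

    def test_single_frame_event_speed_flagged(self):
        ev = self._complete(_record_from_track([(10, 10)]))
        assert ev.propagation_px == 0.0
        assert ev.speed_mm_s == 0.0
        assert ev.speed_undefined

    def test_delay_map_orders_pixels_by_peak_time(self):
        shape, n = (16, 16), 12
        spec = AcquisitionSpec(*shape, n)
        z = np.zeros((*shape, n), dtype=np.float32)
        fp = {}
        for t, c in enumerate(range(4, 10)):
            z[8, c, t + 2] = 10.0
            fp[t + 2] = np.array([[8, c], [8, c + 1]], dtype=np.int32)
        ev = EventRecord(event_id=0, t_start=2, t_end=7, footprints=fp,
                         seed=(8, 4, 2), peak_z=10.0)
        pct = Movie(np.ones((*shape, n), dtype=np.float32), spec)
        event_features(ev, pct, z, spec)
        delays = [ev.delay_map[(8, c)] for c in range(4, 10)]
        assert delays == sorted(delays)


class TestScanSummary:
    def test_three_dynamic_one_static_is_75_percent(self):
        events = []
        for track in ([(5, 5), (5, 9), (5, 13)],) * 3 + ([(20, 20)],):
            spec = AcquisitionSpec(32, 32, 10)
            z = np.ones((32, 32, 10), dtype=np.float32)
            pct = Movie(np.ones((32, 32, 10), dtype=np.float32), spec)
            events.append(event_features(_record_from_track(track), pct, z, spec))
        summary = summarize_scan(events)
        assert summary["pct_dynamic"] == pytest.approx(75.0)
        assert summary["n_events"] == 4

    def test_all_static_scan_flags_undefined_means(self):
        spec = AcquisitionSpec(32, 32, 10)
        z = np.ones((32, 32, 10), dtype=np.float32)
        pct = Movie(np.ones((32, 32, 10), dtype=np.float32), spec)
        events = [event_features(_record_from_track([(8, 8)]), pct, z, spec)]
        summary = summarize_scan(events)
        assert summary["pct_dynamic"] == 0.0
        assert np.isnan(summary["mean_propagation_mm"])

    def test_empty_scan_summary_is_flagged(self):
        summary = summarize_scan([])
        assert summary["n_events"] == 0
        assert summary["undefined"]


def test_train_speed_regresses_position_on_peak_time():
    spec = AcquisitionSpec(32, 32, 200)
    z = np.ones((32, 32, 200), dtype=np.float32)
    pct = Movie(np.ones((32, 32, 200), dtype=np.float32), spec)
    events = []
    # three cycle events, centroid advancing 8 px per 20 frames:
    # 0.8 px/frame * 0.1 mm / 0.4 s = 0.2 mm/s... (8 px / 8 s = 0.1 mm/s)
    for k in range(3):
        rec = _record_from_track([(10, 6 + 8 * k + j) for j in range(3)])
        rec.footprints = {t + 20 * k: fp for t, fp in rec.footprints.items()}
        rec.t_start += 20 * k
        rec.t_end += 20 * k
        rec.seed = (10, 7 + 8 * k, 1 + 20 * k)
        events.append(event_features(rec, pct, z, spec))
    v = train_speed(events, spec)
    assert v == pytest.approx(8 * 0.1 / (20 * 0.4), rel=1e-6)
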