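"""Trajectory taxonomy: delay features, descriptive clustering, and the
rule-based pattern labeller."""

import numpy as np
import pytest

from vasowave.core import AcquisitionSpec
from vasowave.events import EventRecord
from vasowave.patterns import (
    ClusterConfig,
    PatternLabel,
    build_delay_features,
    cluster_patterns,
    label_patterns,
    pattern_frequencies,
)


def _event_with_delays(pixels_delays: dict, dynamic=True, event_id=0):
    """Minimal EventRecord with a preset delay map."""
    ev = EventRecord(
        event_id=event_id, t_start=0, t_end=10,
        footprints={0: np.array(list(pixels_delays), dtype=np.int32)},
        seed=(0, 0, 0), peak_z=10.0,
    )
    ev.delay_map = dict(pixels_delays)
    ev.propagation_px = 10.0 if dynamic else 0.0
    ev.dynamic = dynamic
    return ev


class TestDelayFeatures:
    def test_left_to_right_gradient_gives_positive_horizontal_slope(self):
        delays = {(5, c): 0.4 * c for c in range(10)}
        ev = _event_with_delays(delays)
        binary, dirs, kept = build_delay_features([ev], (16, 16))
        assert kept == [0]
        h, v = dirs[0]
        assert h > 0
        assert abs(v) < 1e-9

    def test_reversed_delays_negate_the_slope(self):
        fwd = _event_with_delays({(5, c): 0.4 * c for c in range(10)})
        rev = _event_with_delays({(5, c): 0.4 * (9 - c) for c in range(10)})
        _, dirs, _ = build_delay_features([fwd, rev], (16, 16))
        assert dirs[0][0] == pytest.approx(-dirs[1][0])

    def test_uniform_delays_give_zero_slopes(self):
        ev = _event_with_delays({(r, c): 1.2 for r in range(4, 8) for c in range(4, 8)})
        _, dirs, _ = build_delay_features([ev], (16, 16))
        assert np.allclose(dirs[0], 0.0)

    def test_small_events_excluded_by_area_gate(self):
        small = _event_with_delays({(5, c): 0.1 * c for c in range(4)})  # 4 px
        big = _event_with_delays({(5, c): 0.1 * c for c in range(10)}, event_id=1)
        binary, dirs, kept = build_delay_features([small, big], (16, 16), min_area_px=5)
        assert kept == [1]
        assert binary.shape[0] == 1


class TestClustering:
    def _zone_events(self, n_per_zone=10, jitter=0):
        rng = np.random.default_rng(0)
        zones = [(2, 2), (2, 20), (20, 2), (20, 20)]
        events, truth = [], []
        for zi, (r0, c0) in enumerate(zones):
            for k in range(n_per_zone):
                delays = {
                    (r0 + dr, c0 + dc): 0.4 * dc
                    for dr in range(6) for dc in range(6)
                }
                events.append(_event_with_delays(delays, event_id=len(events)))
                truth.append(zi)
        return events, truth

    def test_separable_zones_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        events, truth = self._zone_events()
        binary, dirs, _ = build_delay_features(events, (32, 32))
        spatial, _sub = cluster_patterns(binary, dirs, ClusterConfig(seed=0))
        assert adjusted_rand_score(truth, spatial) == pytest.approx(1.0)

    def test_duplicated_events_land_in_the_same_cluster(self):
        events, _ = self._zone_events(n_per_zone=5)
        binary, dirs, _ = build_delay_features(events + events[:1], (32, 32))
        spatial, _ = cluster_patterns(binary, dirs, ClusterConfig(seed=0))
        assert spatial[0] == spatial[-1]

    def test_same_seed_reproduces_assignments(self):
        events, _ = self._zone_events()
        binary, dirs, _ = build_delay_features(events, (32, 32))
        a, sa = cluster_patterns(binary, dirs, ClusterConfig(seed=3))
        b, sb = cluster_patterns(binary, dirs, ClusterConfig(seed=3))
        assert np.array_equal(a, b) and np.array_equal(sa, sb)

    def test_fewer_events_than_clusters_rejected(self):
        events, _ = self._zone_events(n_per_zone=1)
        binary, dirs, _ = build_delay_features(events[:2], (32, 32))
        with pytest.raises(ValueError, match="k_spatial"):
            cluster_patterns(binary, dirs, ClusterConfig(k_spatial=4))


class TestRuleLabels:
    def test_static_event_is_unclassified(self, atlas64):
        ev = _event_with_delays({(30, c): 0.0 for c in range(20, 30)}, dynamic=False)
        assert label_patterns([ev], atlas64, 0.4) == [PatternLabel.UNCLASSIFIED_STATIC]

    def test_outward_cortical_gradient_is_medio_temporal(self, atlas64):
        row = int(np.nonzero(atlas64.tissue_mask("cortex"))[0].mean())
        # right hemisphere, delays increasing laterally
        delays = {(row, 40 + c): 0.4 * c for c in range(15)}
        ev = _event_with_delays(delays)
        assert label_patterns([ev], atlas64, 0.4) == [PatternLabel.MEDIO_TEMPORAL]

    def test_inward_cortical_gradient_is_temporo_medial(self, atlas64):
        row = int(np.nonzero(atlas64.tissue_mask("cortex"))[0].mean())
        delays = {(row, 40 + c): 0.4 * (14 - c) for c in range(15)}
        ev = _event_with_delays(delays)
        assert label_patterns([ev], atlas64, 0.4) == [PatternLabel.TEMPORO_MEDIAL]

    def test_cross_midline_ordering_is_transhemispheric(self, atlas64):
        row = int(np.nonzero(atlas64.tissue_mask("cortex"))[0].mean())
        delays = {(row, 20 + c): 0.4 * c for c in range(25)}  # spans col 31.5
        ev = _event_with_delays(delays)
        assert label_patterns([ev], atlas64, 0.4) == [PatternLabel.TRANSHEMISPHERIC]

    def test_cortex_to_hippocampus_ordering_sets_direction(self, atlas64):
        ctx_row = int(np.nonzero(atlas64.tissue_mask("cortex"))[0].mean())
        hip = np.argwhere(atlas64.mask("Hippocampus", "right"))
        hr, hc = hip.mean(axis=0).astype(int)
        down = {(r, hc): 0.4 * (r - ctx_row) for r in range(ctx_row, hr + 1)}
        up = {(r, hc): 0.4 * (hr - r) for r in range(ctx_row, hr + 1)}
        labs = label_patterns(
            [_event_with_delays(down), _event_with_delays(up, event_id=1)],
            atlas64, 0.4,
        )
        assert labs == [PatternLabel.CORTICO_HIPPOCAMPAL,
                        PatternLabel.HIPPOCAMPO_CORTICAL]

    def test_missing_hemisphere_info_rejected(self, atlas64):
        ev = _event_with_delays({(30, c): 0.1 * c for c in range(10)})
        bare = type(atlas64)(atlas64.labels, atlas64.names, atlas64.hemisphere)
        bare.hemisphere = {}
        with pytest.raises(ValueError, match="hemisphere"):
            label_patterns([ev], bare, 0.4)


class TestFrequencies:
    def test_half_travelling_half_static_splits_50_50(self):
        freqs = pattern_frequencies(
            {"s0": [PatternLabel.MEDIO_TEMPORAL, PatternLabel.UNCLASSIFIED_STATIC]}
        )
        mt = freqs[(freqs.label == "medio_temporal") & (freqs.scan == "s0")]
        assert mt.pct.iloc[0] == pytest.approx(50.0)
        assert mt.pct_excl_unclassified.iloc[0] == pytest.approx(100.0)

    def test_proportions_sum_to_100(self):
        rng = np.random.default_rng(0)
        labels = [list(PatternLabel)[i] for i in rng.integers(0, 7, size=40)]
        freqs = pattern_frequencies({"s": labels})
        assert freqs.pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_invariant_to_event_ordering(self):
        rng = np.random.default_rng(1)
        labels = [list(PatternLabel)[i] for i in rng.integers(0, 7, size=30)]
        a = pattern_frequencies({"s": labels})
        b = pattern_frequencies({"s": labels[::-1]})
        assert a.pct.equals(b.pct)

    def test_empty_scan_flagged(self):
        freqs = pattern_frequencies({"empty": []})
        assert freqs.empty_scan.all()
        assert freqs.pct.isna().all()
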