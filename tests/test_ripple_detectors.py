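"""Detector presets, the shared detection engine, IED handling, and
event utilities."""

import numpy as np
import pytest

import ripplefloor as rf
from ripplefloor.ripple_detectors import DetectedEvent


def make_event(trough, start, end, peak=3.0, freq=90.0, det="1"):
    return DetectedEvent(trough, start, end, peak, freq, det)


def fixture_with_burst(chi, amp, freq=100.0, dur=0.1, t=10.0, seed=9, length=60.0):
    sched = rf.StateSchedule([(0, length, "s")])
    spec = rf.FixtureSpec(sched, {"s": chi},
                          injected_ripples=[(t, freq, dur, amp)], seed=seed)
    trace, _ = rf.generate_fixture(spec)
    return trace


class TestPresets:
    @pytest.mark.parametrize("det_id,attr,expected", [
        (1, "duration", (0.025, 0.2)),
        (1, "band", (80.0, 120.0)),
        (1, "merge_gap", 0.5),
        (1, "ied_exclusion", 2.5),
        (2, "band", (80.0, 100.0)),
        (2, "duration", (0.038, 0.1)),
        (2, "threshold_rule", ("percentile", 99.0)),
        (3, "merge_gap", 0.015),
        (3, "duration", (0.025, np.inf)),
        (4, "band", (70.0, 180.0)),
        (4, "amplitude_clip", 4.0),
        (4, "duration", (0.02, 0.2)),
        (5, "duration", (0.02, 0.2)),
        (5, "merge_gap", 0.1),
        (5, "ied_exclusion", 1.0),
    ])
    def test_published_parameters(self, det_id, attr, expected):
        assert getattr(rf.preset(det_id), attr) == expected

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError):
            rf.preset(6)


class TestDetectRipples:
    def test_white_noise_yields_detections(self, white_trace):
        events = rf.detect_ripples(white_trace, rf.preset(1))
        assert len(events) > 0
        assert all(e.start < e.end for e in events)
        assert all(t1.trough_time <= t2.trough_time
                   for t1, t2 in zip(events, events[1:]))

    def test_injected_burst_detected_once(self):
        # strong burst on a steep background, permissive detector 3
        trace = fixture_with_burst(-3.0, amp=5.0)
        events = rf.detect_ripples(trace, rf.preset(3))
        near = [e for e in events if abs(e.trough_time - 10.0) < 0.05]
        assert len(near) == 1

    def test_amplitude_window_admits_calibrated_burst(self):
        # burst calibrated (via the envelope oracle) to land inside
        # detector 1's 2-4 SD window and pass its frequency criterion
        trace = fixture_with_burst(-1.5, amp=0.35, freq=110.0, dur=0.15)
        events = rf.detect_ripples(trace, rf.preset(1))
        near = [e for e in events if abs(e.trough_time - 10.0) < 0.06]
        assert len(near) == 1
        assert 2.0 <= near[0].peak_amplitude <= 4.0

    def test_amplitude_window_rejects_oversized_burst(self):
        # an 8 SD burst exceeds the 4 SD envelope cap
        trace = fixture_with_burst(-1.5, amp=8.0, freq=110.0, dur=0.15)
        events = rf.detect_ripples(trace, rf.preset(1))
        assert [e for e in events if abs(e.trough_time - 10.0) < 0.06] == []

    def test_durations_within_bounds(self, white_trace):
        for det in (2, 3):
            cfg = rf.preset(det)
            for e in rf.detect_ripples(white_trace, cfg):
                assert e.duration >= cfg.duration[0] - 1e-9
                if np.isfinite(cfg.duration[1]):
                    assert e.duration <= cfg.duration[1] + 1e-9

    @pytest.mark.parametrize("det", [1, 3, 5])
    def test_scale_invariance_of_z_normalized_detectors(self, det):
        trace = rf.generate_colored_noise(-2.0, 60, 1000, seed=31)
        scaled = rf.SignalTrace(1234.5 * trace.samples, 1000.0)
        a = rf.detect_ripples(trace, rf.preset(det))
        b = rf.detect_ripples(scaled, rf.preset(det))
        assert [e.trough_time for e in a] == [e.trough_time for e in b]

    def test_rate_too_low_rejected(self):
        tr = rf.SignalTrace(np.random.default_rng(0).standard_normal(3000), 200.0)
        with pytest.raises(ValueError):
            rf.detect_ripples(tr, rf.preset(1))

    def test_short_trace_rejected(self):
        tr = rf.SignalTrace(np.random.default_rng(0).standard_normal(3000), 1000.0)
        with pytest.raises(ValueError):
            rf.detect_ripples(tr, rf.preset(1))

    def test_constant_trace_rejected(self):
        tr = rf.SignalTrace(np.ones(20_000), 1000.0)
        with pytest.raises(rf.DegenerateSignalError):
            rf.detect_ripples(tr, rf.preset(1))


class TestMergeEvents:
    def test_within_gap_merged(self):
        events = [make_event(1.005, 1.000, 1.010), make_event(1.02, 1.015, 1.030)]
        merged = rf.merge_events(events, 0.015)
        assert len(merged) == 1
        assert merged[0].start == 1.000 and merged[0].end == 1.030

    def test_outside_gap_kept(self):
        events = [make_event(1.005, 1.000, 1.010), make_event(1.02, 1.015, 1.030)]
        assert len(rf.merge_events(events, 0.001)) == 2

    def test_idempotent(self):
        events = [make_event(1.0, 0.99, 1.01), make_event(1.02, 1.015, 1.03),
                  make_event(5.0, 4.99, 5.01)]
        once = rf.merge_events(events, 0.015)
        twice = rf.merge_events(once, 0.015)
        assert once == twice

    def test_keeps_strongest_peak(self):
        events = [make_event(1.0, 0.99, 1.01, peak=2.5),
                  make_event(1.02, 1.015, 1.03, peak=3.5)]
        merged = rf.merge_events(events, 0.015)
        assert merged[0].peak_amplitude == 3.5
        assert merged[0].trough_time == 1.02


class TestIeds:
    def test_sharp_transient_detected(self):
        sched = rf.StateSchedule([(0, 60, "s")])
        spec = rf.FixtureSpec(sched, {"s": -3.0}, injected_ieds=[(30.0, 8.0)], seed=9)
        trace, _ = rf.generate_fixture(spec)
        ieds = rf.detect_ieds(trace)
        assert any(abs(e.trough_time - 30.0) < 0.1 for e in ieds)

    def test_nearby_transients_concatenated(self):
        sched = rf.StateSchedule([(0, 60, "s")])
        spec = rf.FixtureSpec(sched, {"s": -3.0},
                              injected_ieds=[(30.0, 8.0), (30.5, 8.0)], seed=9)
        trace, _ = rf.generate_fixture(spec)
        near = [e for e in rf.detect_ieds(trace) if 29 < e.trough_time < 32]
        assert len(near) == 1

    def test_colored_noise_density_finite(self, brown_trace):
        ieds = rf.detect_ieds(brown_trace)
        density = len(ieds) / brown_trace.duration
        assert np.isfinite(density) and density >= 0


class TestExcludeNearIeds:
    def test_nearby_ripple_removed(self):
        ripples = [make_event(10.0, 9.99, 10.01)]
        ieds = [make_event(11.0, 10.99, 11.01, det="IED")]
        assert rf.exclude_near_ieds(ripples, ieds, 2.5) == []

    def test_distant_ripple_kept(self):
        ripples = [make_event(10.0, 9.99, 10.01)]
        ieds = [make_event(20.0, 19.99, 20.01, det="IED")]
        assert rf.exclude_near_ieds(ripples, ieds, 2.5) == ripples

    def test_empty_ied_list_is_identity(self):
        ripples = [make_event(10.0, 9.99, 10.01)]
        assert rf.exclude_near_ieds(ripples, [], 2.5) == ripples


class TestAlignToTrough:
    def test_pure_tone_trough(self):
        t = np.arange(30_000) / 1000.0
        trace = rf.SignalTrace(np.sin(2 * np.pi * 90 * t), 1000.0)
        # envelope max placed mid-cycle; nearest sine minimum is at
        # t = (k + 3/4) / 90
        ev = make_event(10.000, 9.990, 10.012)
        aligned = rf.align_to_trough(ev, trace)
        k = round(aligned.trough_time * 90 - 0.75)
        expected = (k + 0.75) / 90
        assert abs(aligned.trough_time - expected) <= 1.0 / 1000.0

    def test_idempotent(self):
        t = np.arange(30_000) / 1000.0
        trace = rf.SignalTrace(np.sin(2 * np.pi * 90 * t), 1000.0)
        once = rf.align_to_trough(make_event(10.0, 9.99, 10.012), trace)
        twice = rf.align_to_trough(once, trace)
        assert once.trough_time == twice.trough_time

    def test_tie_breaks_earlier(self):
        # two equal minima equidistant from the event's reference point
        x = np.zeros(1000)
        x[100] = -1.0
        x[300] = -1.0
        trace = rf.SignalTrace(x + 0.001 * np.arange(1000) * 0, 1000.0)
        ev = make_event(0.200, 0.050, 0.350)
        aligned = rf.align_to_trough(ev, trace)
        assert aligned.trough_time == pytest.approx(0.100)

    def test_no_interior_minimum_raises(self):
        trace = rf.SignalTrace(np.arange(1000, dtype=float), 1000.0)
        with pytest.raises(ValueError):
            rf.align_to_trough(make_event(0.5, 0.4, 0.6), trace)


class TestEventLockedAverage:
    def test_identical_bursts_average_to_single_snippet(self):
        sched = rf.StateSchedule([(0, 120, "s")])
        times = [20.0, 50.0, 80.0]
        spec = rf.FixtureSpec(sched, {"s": -3.0},
                              injected_ripples=[(t, 100.0, 0.1, 6.0) for t in times],
                              seed=9)
        trace, _ = rf.generate_fixture(spec)
        events = [make_event(t, t - 0.05, t + 0.05) for t in times]
        lags, avg, n = rf.event_locked_average(events, trace)
        assert n == 3
        mid = np.abs(lags) < 0.05
        assert np.ptp(avg[mid]) > 2 * np.std(avg[(lags < -2.0)])

    def test_edge_events_skipped_and_counted(self, brown_trace):
        events = [make_event(1.0, 0.99, 1.01), make_event(300.0, 299.99, 300.01)]
        _, _, n = rf.event_locked_average(events, brown_trace)
        assert n == 1

    def test_no_eligible_events_raises(self, brown_trace):
        with pytest.raises(ValueError):
            rf.event_locked_average([make_event(0.5, 0.49, 0.51)], brown_trace)


class TestEventTables:
    def test_round_trip(self, tmp_path):
        events = [make_event(1.5, 1.45, 1.55, peak=2.7, freq=95.0),
                  make_event(9.1, 9.05, 9.2, peak=3.1, freq=88.0, det="3")]
        path = tmp_path / "events.tsv"
        rf.write_events(events, path)
        back = rf.read_events(path)
        assert len(back) == 2
        assert back[0].trough_time == 1.5
        assert back[1].detector_id == "3"
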