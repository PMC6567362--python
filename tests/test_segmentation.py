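"""Threshold-trigger segmentation, threshold tuning, online detection."""

import numpy as np
import pytest

from motionwarp import (MotionGeneratorConfig, SegmentationConfig,
                        SegmentEvent, build_averaged_mpps, detect_online,
                        generate_dataset, generate_stream,
                        optimize_thresholds, segment_stream, segmentation_f1,
                        signal_variation)


def config(start=0.05, stop=0.02, **kw):
    return SegmentationConfig(start_threshold=start, stop_threshold=stop, **kw)


class TestConfig:
    def test_stop_above_start_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(start_threshold=0.1, stop_threshold=0.2)

    def test_default_hold_is_ten_samples_at_20hz(self):
        assert config().hold_samples == 10
        assert config().window_samples == 5


class TestSignalVariation:
    def test_constant_stream_zero(self):
        v = signal_variation(np.full(40, 3.0), config())
        assert np.allclose(v, 0.0)

    def test_step_change_positive(self):
        stream = np.concatenate([np.zeros(20), np.ones(20)])
        v = signal_variation(stream, config())
        assert v[20] > 0

    def test_hand_computed_rolling_sd(self):
        stream = np.array([0.0, 0.0, 1.0, 1.0, 0.0])
        cfg = config(variation_window=3 / 20.0)  # 3-sample window
        v = signal_variation(stream, cfg)
        expected = [np.std([0, 0, 1]), np.std([0, 0, 1]), np.std([0, 0, 1]),
                    np.std([0, 1, 1]), np.std([1, 1, 0])]
        assert np.allclose(v, expected)

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError):
            signal_variation(np.ones(3), config())


def burst_stream(quiet=20, burst=30, amplitude=1.0, gap=None):
    """Quiet-burst(-gap-burst)-quiet test stream; burst is a noisy sinusoid."""
    rng = np.random.default_rng(0)
    t = np.arange(burst) / 20.0
    b = amplitude * np.sin(2 * np.pi * 3 * t)
    parts = [np.zeros(quiet), b]
    if gap is not None:
        parts += [np.zeros(gap), b]
    parts.append(np.zeros(quiet))
    return np.concatenate(parts)


class TestSegmentStream:
    def test_quiet_stream_empty(self):
        assert segment_stream(np.zeros(100), config()) == []

    def test_single_burst_single_segment(self):
        stream = burst_stream()
        events = segment_stream(stream, config())
        assert len(events) == 1
        ev = events[0]
        assert ev.start_index <= 30 and ev.end_index >= 40  # brackets burst

    def test_short_gap_merges_bursts(self):
        # 0.4 s = 8 samples of quiet < 10-sample hold: one merged segment
        stream = burst_stream(gap=8)
        assert len(segment_stream(stream, config())) == 1

    def test_long_gap_separates_bursts(self):
        stream = burst_stream(quiet=30, gap=30)
        assert len(segment_stream(stream, config())) == 2

    def test_segments_ordered_and_disjoint(self):
        stream = burst_stream(quiet=30, gap=30)
        events = segment_stream(stream, config())
        for a, b in zip(events, events[1:]):
            assert a.end_index < b.start_index

    def test_hold_monotonicity(self):
        """Shortening the hold never decreases the segment count."""
        stream = burst_stream(quiet=30, gap=9)
        counts = []
        for hold in (1.0, 0.5, 0.3, 0.1, 0.05):
            cfg = config(hold_duration=hold)
            counts.append(len(segment_stream(stream, cfg)))
        assert counts == sorted(counts)

    def test_open_segment_closed_at_stream_end(self):
        stream = np.concatenate([np.zeros(20),
                                 np.sin(np.linspace(0, 20, 60))])
        events = segment_stream(stream, config())
        assert events and events[-1].end_index == stream.size


class TestEventInvariants:
    def test_reversed_span_rejected(self):
        with pytest.raises(ValueError):
            SegmentEvent(5, 3)


@pytest.fixture(scope="module")
def planted():
    cfg = MotionGeneratorConfig(seed=5, noise_sd=0.0, quiet_noise_sd=0.0)
    plan = [("sit_down", 1.0), ("stand_up", 1.0), ("walk", 1.0)]
    return generate_stream(plan, cfg)


class TestOptimizeThresholds:
    def test_recovers_perfect_separator(self, planted):
        stream, truth = planted
        best = optimize_thresholds([(stream, truth)], seed=0,
                                   n_particles=12, n_iterations=25)
        events = segment_stream(stream, best)
        assert segmentation_f1(events, truth) == 1.0
        assert best.stop_threshold <= best.start_threshold

    def test_deterministic_under_seed(self, planted):
        a = optimize_thresholds([planted], seed=4, n_particles=8,
                                n_iterations=10)
        b = optimize_thresholds([planted], seed=4, n_particles=8,
                                n_iterations=10)
        assert a.start_threshold == b.start_threshold
        assert a.stop_threshold == b.stop_threshold

    def test_pso_at_least_matches_grid_search(self, planted):
        stream, truth = planted
        pso = optimize_thresholds([(stream, truth)], seed=0)
        grid = optimize_thresholds([(stream, truth)], use_grid=True)
        f = lambda c: segmentation_f1(segment_stream(stream, c), truth)
        assert f(pso) >= f(grid) - 1e-9

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            optimize_thresholds([(np.zeros(50), [])])


class TestDetectOnline:
    def test_planted_motions_recovered_with_labels(self, planted):
        stream, truth = planted
        data = generate_dataset(10, MotionGeneratorConfig(seed=9,
                                                          noise_sd=0.05))
        tset = build_averaged_mpps(data, method="dft")
        events = detect_online(stream, tset, config())
        assert len(events) == len(truth)
        for ev, (ts, te, lab) in zip(events, truth):
            overlap = max(0, min(ev.end_index, te) - max(ev.start_index, ts) + 1)
            assert overlap >= 0.5 * (te - ts + 1)
            assert ev.label == lab
            assert ev.cost >= 0

    def test_quiet_stream_no_events(self):
        data = generate_dataset(3, MotionGeneratorConfig(seed=2))
        tset = build_averaged_mpps(data)
        assert detect_online(np.zeros(100), tset, config()) == []

    def test_one_event_per_planted_motion_at_low_noise(self):
        cfg = MotionGeneratorConfig(seed=21, noise_sd=0.05,
                                    quiet_noise_sd=0.01)
        plan = [("sit_down", 1.5), ("walk", 1.5), ("stand_up", 1.5),
                ("sit_down", 1.5)]
        stream, truth = generate_stream(plan, cfg)
        events = segment_stream(stream, config(start=0.08, stop=0.04))
        assert len(events) == len(truth)


def test_batch_accuracy_table():
    """A batch of synthetic streams yields a per-motion accuracy table
    (count, missed, error, accuracy%) for the exception motions."""
    gen = MotionGeneratorConfig(seed=31, noise_sd=0.05, quiet_noise_sd=0.01)
    data = generate_dataset(10, gen)
    tset = build_averaged_mpps(data, method="dft")
    cfg = config(start=0.08, stop=0.04)
    stats = {3: [0, 0, 0], 2: [0, 0, 0]}  # planted, missed, mislabeled
    for trial in range(6):
        c = MotionGeneratorConfig(seed=500 + trial, noise_sd=0.05,
                                  quiet_noise_sd=0.01)
        plan = [("sit_down", 1.5), ("stand_up", 1.5), ("walk", 1.5)]
        stream, truth = generate_stream(plan, c)
        events = detect_online(stream, tset, cfg)
        for ts, te, lab in truth:
            if lab not in stats:
                continue  # walking counts as normal, not an exception
            stats[lab][0] += 1
            hit = [e for e in events
                   if max(0, min(e.end_index, te) - max(e.start_index, ts) + 1)
                   >= 0.5 * (te - ts + 1)]
            if not hit:
                stats[lab][1] += 1
            elif hit[0].label != lab:
                stats[lab][2] += 1
    for lab, (count, missed, error) in stats.items():
        assert count == 6
        accuracy = 100.0 * (count - missed - error) / count
        assert accuracy >= 50.0
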