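"""Threshold-trigger segmentation of a continuous sensor stream.

Online matching needs candidate segments cut from the raw stream first.  A
signal-variation statistic (rolling standard deviation over a short window)
drives a two-threshold trigger: a segment opens when the variation rises
above the start threshold, and closes once the variation has stayed below
the stop threshold for a minimum hold time (0.5 s by default).  The hold
window itself is excluded from the segment body, so matched patterns are
not padded with trailing quiet.

The two thresholds are data-dependent; ``optimize_thresholds`` tunes them
on streams with known motion spans by maximizing segment-level F1 with a
particle-swarm search (global-best topology), with a plain grid search
available as a fallback.

``detect_online`` chains segmentation with template matching: each segment
body is min-max normalized and labeled by minimum total warping cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .dtw import dtw_cost
from .equalize import normalize_unit_interval
from .templates import TemplateSet

__all__ = ["SegmentationConfig", "SegmentEvent", "signal_variation",
           "segment_stream", "segmentation_f1", "optimize_thresholds",
           "detect_online"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Trigger thresholds and timing for stream framing.

    ``start_threshold`` and ``stop_threshold`` are in variation units
    (standard deviation of the signal over ``variation_window`` seconds);
    the stop threshold may not exceed the start threshold.
    """

    start_threshold: float
    stop_threshold: float
    hold_duration: float = 0.5
    variation_window: float = 0.25
    sampling_rate: float = 20.0

    def __post_init__(self):
        if self.hold_duration <= 0:
            raise ValueError("hold_duration must be positive")
        if self.start_threshold < 0 or self.stop_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.stop_threshold > self.start_threshold:
            raise ValueError("stop_threshold must not exceed start_threshold")
        if self.variation_window <= 0 or self.sampling_rate <= 0:
            raise ValueError("window and sampling rate must be positive")

    @property
    def window_samples(self) -> int:
        return max(1, int(round(self.variation_window * self.sampling_rate)))

    @property
    def hold_samples(self) -> int:
        return max(1, int(round(self.hold_duration * self.sampling_rate)))


@dataclass
class SegmentEvent:
    """One framed (optionally labeled) segment; indices 1-based inclusive."""

    start_index: int
    end_index: int
    label: object = None
    cost: float = None

    def __post_init__(self):
        if self.start_index > self.end_index:
            raise ValueError("segment start after end")

    def span(self):
        return self.start_index, self.end_index


def signal_variation(stream, config: SegmentationConfig) -> np.ndarray:
    """Right-aligned rolling standard deviation (population, ddof=0).

    The first ``window - 1`` positions, where no full window fits, are
    padded with the first valid value so the series has the stream's length.
    """
    x = np.asarray(stream, dtype=float).ravel()
    w = config.window_samples
    if x.size < w:
        raise ValueError(f"stream length {x.size} shorter than the "
                         f"variation window ({w} samples)")
    # rolling mean of x and x^2 via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    mean = (c1[w:] - c1[:-w]) / w
    meansq = (c2[w:] - c2[:-w]) / w
    var = np.maximum(meansq - mean * mean, 0.0)
    sd = np.sqrt(var)
    return np.concatenate((np.full(w - 1, sd[0]), sd))


def segment_stream(stream, config: SegmentationConfig) -> list:
    """Frame candidate segments from a stream with the two-threshold trigger.

    A segment opens at the first sample whose variation exceeds the start
    threshold and closes when the variation has remained below the stop
    threshold for at least the hold duration; the hold period is excluded
    from the segment body.  A segment still open at the end of the stream
    is closed at the final sample.  Returns non-overlapping, ordered
    :class:`SegmentEvent` objects with 1-based inclusive indices.
    """
    v = signal_variation(stream, config)
    hold = config.hold_samples
    events = []
    open_at = None
    below_run = 0
    for i, vi in enumerate(v):
        if open_at is None:
            if vi > config.start_threshold:
                open_at = i
                below_run = 0
        else:
            if vi < config.stop_threshold:
                below_run += 1
                if below_run >= hold:
                    end = i - below_run  # last sample before the hold window
                    if end >= open_at:
                        events.append(SegmentEvent(open_at + 1, end + 1))
                    open_at = None
                    below_run = 0
            else:
                below_run = 0
    if open_at is not None:
        events.append(SegmentEvent(open_at + 1, len(v)))
    return events


def _overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def segmentation_f1(events, truth) -> float:
    """Segment-level F1 between detected events and ground-truth spans.

    A detected segment matches a true span when their overlap covers at
    least half of the true span; matching is greedy and one-to-one in
    stream order.
    """
    truth = [t[:2] for t in truth]
    spans = [e.span() for e in events]
    matched_pred = set()
    tp = 0
    for t in truth:
        for j, p in enumerate(spans):
            if j in matched_pred:
                continue
            if _overlap(t, p) >= 0.5 * (t[1] - t[0] + 1):
                matched_pred.add(j)
                tp += 1
                break
    fp = len(spans) - len(matched_pred)
    fn = len(truth) - tp
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def _objective(start, stop, streams, base: SegmentationConfig) -> float:
    f1s = []
    for stream, truth in streams:
        cfg = replace(base, start_threshold=start, stop_threshold=stop)
        f1s.append(segmentation_f1(segment_stream(stream, cfg), truth))
    return float(np.mean(f1s))


def optimize_thresholds(labeled_streams, base_config: SegmentationConfig = None,
                        n_particles=20, n_iterations=50, seed=0,
                        use_grid=False) -> SegmentationConfig:
    """Choose start/stop thresholds maximizing mean segment-level F1.

    Parameters
    ----------
    labeled_streams : list of (stream, truth)
        ``truth`` is a list of (start, end[, label]) 1-based spans.
    base_config : SegmentationConfig, optional
        Timing parameters to keep; thresholds are overwritten.
    n_particles, n_iterations : int
        Particle-swarm size and budget (inertia 0.7, cognitive and social
        coefficients 1.5, global-best topology).
    seed : int
        Makes the swarm deterministic.
    use_grid : bool
        Replace the swarm with a dense grid search over the same bounds.

    The search space is (start, r) with stop = r * start, r in [0, 1], which
    enforces stop <= start by construction.
    """
    streams = [(np.asarray(s, dtype=float).ravel(), list(t))
               for s, t in labeled_streams]
    if not streams or all(not t for _, t in streams):
        raise ValueError("threshold optimization needs ground-truth spans")
    base = base_config or SegmentationConfig(start_threshold=0.0,
                                             stop_threshold=0.0)
    hi = max(signal_variation(s, base).max() for s, _ in streams)
    lo = 0.0
    bounds = np.array([[lo, hi], [0.0, 1.0]])

    def score(p):
        return _objective(p[0], p[1] * p[0], streams, base)

    if use_grid:
        starts = np.linspace(lo + hi * 1e-3, hi, 40)
        ratios = np.linspace(0.0, 1.0, 11)
        best, best_p = -1.0, None
        for s, r in itertools.product(starts, ratios):
            f = score((s, r))
            if f > best:
                best, best_p = f, (s, r)
        p = best_p
    else:
        rng = np.random.default_rng(seed)
        dim = 2
        pos = rng.uniform(bounds[:, 0], bounds[:, 1], (n_particles, dim))
        vel = np.zeros((n_particles, dim))
        pbest = pos.copy()
        pbest_f = np.array([score(p) for p in pos])
        g = int(np.argmax(pbest_f))
        gbest, gbest_f = pbest[g].copy(), pbest_f[g]
        w, c1, c2 = 0.7, 1.5, 1.5
        for _ in range(n_iterations):
            r1 = rng.uniform(size=(n_particles, dim))
            r2 = rng.uniform(size=(n_particles, dim))
            vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
            pos = np.clip(pos + vel, bounds[:, 0], bounds[:, 1])
            for i in range(n_particles):
                f = score(pos[i])
                if f > pbest_f[i]:
                    pbest_f[i] = f
                    pbest[i] = pos[i].copy()
                    if f > gbest_f:
                        gbest_f = f
                        gbest = pos[i].copy()
        p = gbest
    return replace(base, start_threshold=float(p[0]),
                   stop_threshold=float(p[1] * p[0]))


def detect_online(stream, template_set: TemplateSet,
                  config: SegmentationConfig) -> list:
    """Segment a stream and label every segment by template matching.

    Each segment body is min-max normalized onto [0, 1] and matched against
    every template; the event carries the winning label and its total
    warping cost.
    """
    if not template_set.templates:
        raise ValueError("no templates loaded")
    x = np.asarray(stream, dtype=float).ravel()
    events = []
    for ev in segment_stream(x, config):
        body = x[ev.start_index - 1:ev.end_index]
        q = normalize_unit_interval(body)
        best_label, best_cost = None, np.inf
        for label in sorted(template_set.templates, key=str):
            c = dtw_cost(q, template_set.templates[label])
            if c < best_cost:
                best_label, best_cost = label, c
        events.append(SegmentEvent(ev.start_index, ev.end_index,
                                   label=best_label, cost=best_cost))
    return events
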