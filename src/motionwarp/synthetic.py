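"""Synthetic frontal-axis motion generator.

Emulates single-channel acceleration traces of a body-worn inertial sensor
sampled at 20 Hz, for three motion categories:

``sit_down``
    A biphasic pulse — a positive lobe (forward lean / descent onset)
    followed by a negative lobe (deceleration into the seat), shaped as one
    sine period under a Hann window.
``stand_up``
    The exact polarity mirror of ``sit_down``, consistent with reversing the
    same motion along the frontal axis.
``walk``
    A damped ~2 Hz sinusoid, the cadence-band oscillation of gait.

The shapes are synthetic prototypes, not traces extracted from any
recording.  Realism enters through three randomizations: a speed factor
that rescales the motion duration (so the *length* of the sampled sequence
varies, the premise the warping alignment exists to absorb), an amplitude
factor, and additive white Gaussian noise.  All randomness is seeded and
every level (sequence, dataset, stream) is reproducible.

Default condition: 20 Hz, 2.0 s base duration, +/-30 % speed jitter,
+/-10 % amplitude jitter, noise standard deviation 0.1 signal units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import MotionSequence

__all__ = ["MotionGeneratorConfig", "CATEGORIES", "LABEL_CODES",
           "generate_motion", "generate_dataset", "generate_stream"]

#: categories with their numeric label codes (stand-up 2, sit-down 3,
#: walking 4, following the data-collection sub-function numbering)
LABEL_CODES = {"stand_up": 2, "sit_down": 3, "walk": 4}
CATEGORIES = tuple(LABEL_CODES)


@dataclass(frozen=True)
class MotionGeneratorConfig:
    """Generator condition; defaults define the standard synthetic setting.

    Attributes
    ----------
    sampling_rate : float, Hz
    base_duration : float, seconds per motion before speed scaling
    speed_jitter : float
        Duration scale drawn uniformly from [1 - j, 1 + j].
    amplitude_jitter : float
        Amplitude scale drawn uniformly from [1 - j, 1 + j].
    noise_sd : float
        Additive white-noise standard deviation, signal units.
    quiet_noise_sd : float
        Baseline noise between motions in a continuous stream.
    seed : int
        Root seed; per-sequence seeds are derived from it.
    """

    sampling_rate: float = 20.0
    base_duration: float = 2.0
    speed_jitter: float = 0.3
    amplitude_jitter: float = 0.1
    noise_sd: float = 0.1
    quiet_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.speed_jitter < 0 or self.amplitude_jitter < 0:
            raise ValueError("jitters must be non-negative")
        if self.noise_sd < 0 or self.quiet_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        min_len = self.sampling_rate * self.base_duration * (1 - self.speed_jitter)
        if min_len < 4:
            raise ValueError("configuration can yield sequences shorter than "
                             "4 samples")


def _prototype(category: str, t: np.ndarray, duration: float) -> np.ndarray:
    """Noise-free unit-amplitude waveform at times ``t`` in [0, duration]."""
    u = t / duration  # phase in [0, 1]
    if category == "sit_down":
        return np.sin(2 * np.pi * u) * np.sin(np.pi * u) ** 2
    if category == "stand_up":
        return -np.sin(2 * np.pi * u) * np.sin(np.pi * u) ** 2
    if category == "walk":
        return 0.6 * np.sin(2 * np.pi * 2.0 * t) * np.exp(-t / (0.75 * duration))
    raise ValueError(f"unknown motion category {category!r}")


def generate_motion(category: str, config: MotionGeneratorConfig = None,
                    seed=None) -> MotionSequence:
    """One labeled motion sequence with speed, amplitude and noise variation.

    ``seed`` overrides ``config.seed`` for this one draw.  With all jitters
    and noise at zero the output is the deterministic prototype, and
    ``stand_up`` is the pointwise negation of ``sit_down``.
    """
    config = config or MotionGeneratorConfig()
    if category not in LABEL_CODES:
        raise ValueError(f"unknown motion category {category!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    speed = 1.0 + config.speed_jitter * rng.uniform(-1, 1)
    amp = 1.0 + config.amplitude_jitter * rng.uniform(-1, 1)
    duration = config.base_duration * speed
    n = max(4, int(round(duration * config.sampling_rate)))
    t = np.arange(n) / config.sampling_rate
    wave = amp * _prototype(category, t, duration)
    if config.noise_sd > 0:
        wave = wave + rng.normal(0.0, config.noise_sd, n)
    return MotionSequence(wave, label=LABEL_CODES[category],
                          sampling_rate=config.sampling_rate)


def generate_dataset(n_per_category: int, config: MotionGeneratorConfig = None,
                     categories=CATEGORIES) -> list:
    """``n_per_category`` labeled sequences per category, shuffled.

    Per-sample seeds are drawn sequentially from the root seed so the whole
    dataset is reproducible and individual samples are independent.
    """
    config = config or MotionGeneratorConfig()
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    root = np.random.default_rng(config.seed)
    samples = []
    for cat in categories:
        for _ in range(n_per_category):
            samples.append(generate_motion(cat, config,
                                           seed=int(root.integers(2**31))))
    order = np.random.default_rng(config.seed + 1).permutation(len(samples))
    return [samples[i] for i in order]


def generate_stream(motion_plan, config: MotionGeneratorConfig = None):
    """A continuous stream with planted motions and its ground truth.

    Parameters
    ----------
    motion_plan : list of (category, gap_seconds)
        Each entry plants a quiet gap of ``gap_seconds`` followed by one
        motion of ``category``.  A trailing quiet tail of the last gap
        length is appended.
    config : MotionGeneratorConfig

    Returns
    -------
    (ndarray, list of (start, end, label))
        The stream and the true spans as 1-based inclusive sample indices.
    """
    config = config or MotionGeneratorConfig()
    rng = np.random.default_rng(config.seed)

    def quiet(seconds):
        n = int(round(seconds * config.sampling_rate))
        if config.quiet_noise_sd > 0:
            return rng.normal(0.0, config.quiet_noise_sd, n)
        return np.zeros(n)

    chunks, truth = [], []
    pos = 0
    last_gap = 1.0
    for category, gap in motion_plan:
        g = quiet(gap)
        chunks.append(g)
        pos += g.size
        motion = generate_motion(category, config,
                                 seed=int(rng.integers(2**31)))
        chunks.append(motion.samples)
        truth.append((pos + 1, pos + len(motion), motion.label))
        pos += len(motion)
        last_gap = gap
    chunks.append(quiet(last_gap))
    stream = np.concatenate(chunks) if chunks else np.zeros(0)
    return stream, truth
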