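"""Core containers for motion signals and warping results.

A motion sequence is a single-channel acceleration trace (frontal axis of a
body-worn inertial sensor, 20 Hz by default) of arbitrary length, optionally
carrying a category label.  Sequences of different lengths are compared by
dynamic time warping, so no container here ever assumes a common length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MotionSequence", "WarpingResult"]


@dataclass(frozen=True)
class MotionSequence:
    """A variable-length, real-valued sample vector with an optional label.

    Parameters
    ----------
    samples : array-like of float
        Ordered acceleration samples in arbitrary but consistent units.
    label : int or str, optional
        Motion category code (e.g. 2 = stand-up, 3 = sit-down, 4 = walking).
    sampling_rate : float, default 20.0
        Samples per second.
    """

    samples: np.ndarray
    label: object = None
    sampling_rate: float = 20.0

    def __post_init__(self):
        arr = np.array(self.samples, dtype=float)  # copy: frozen below
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a motion sequence must be a non-empty 1-D vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError("motion sequence contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        arr.flags.writeable = False
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.size)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.samples, dtype=dtype)

    def with_samples(self, samples) -> "MotionSequence":
        """Return a copy carrying the same label/rate but new samples."""
        return MotionSequence(samples, label=self.label,
                              sampling_rate=self.sampling_rate)


@dataclass(frozen=True)
class WarpingResult:
    """Outcome of aligning two sequences by dynamic time warping.

    Attributes
    ----------
    cost_matrix : (N, M) ndarray
        Accumulated minimum cost sigma(n, m); entry (N, M) is the total cost.
    path : list of (int, int)
        Optimal warping path as 1-based index pairs from (1, 1) to (N, M),
        monotone in both coordinates.
    total_cost : float
        Sum of local squared differences along ``path``; lower means more
        similar.
    """

    cost_matrix: np.ndarray
    path: list = field(default_factory=list)
    total_cost: float = 0.0
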