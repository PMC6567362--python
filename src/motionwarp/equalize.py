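"""Length equalization of variable-length sequences.

A feed-forward network needs fixed-length inputs, but motion traces recorded
at a fixed sampling rate vary in length with motion speed.  Two preprocessors
map an N-sample sequence to a common target length M >= N:

``dft_interpolate``
    Frequency-domain zero padding.  The N-point DFT is split in half (first
    N/2 and last N/2 coefficients for even N; first (N+1)/2 and last (N-1)/2
    for odd N), M - N zeros are inserted between the halves, and the M-point
    inverse DFT is taken.  The inverse transform's 1/M factor is kept as is,
    so amplitudes shrink by N/M; downstream min-max normalization removes
    that scale.  For an integer upsampling ratio M = r*N the output at
    positions 1 + r*(n-1) equals (N/M) * x_n exactly.

``convolutional_equalize``
    Full discrete convolution with an all-equal kernel of length
    Q = M - N + 1, i.e. a moving average whose length is chosen
    automatically from the input length.  The full convolution of lengths N
    and Q has length N + Q - 1 = M.

Both are upsamplers only: M < N is rejected.

After equalization, sequences are min-max normalized to [0, 1]
(``normalize_unit_interval``) so that template averaging and network inputs
are amplitude-comparable.

Scikit-learn transformer wrappers (:class:`DFTInterpolator`,
:class:`ConvolutionalEqualizer`) expose the same operations for use in
pipelines; they accept lists of ragged 1-D sequences and emit a dense
(n_sequences, M) array.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence import MotionSequence

__all__ = [
    "dft_forward",
    "dft_inverse",
    "spectrum_zero_pad",
    "dft_interpolate",
    "convolutional_equalize",
    "normalize_unit_interval",
    "equalize",
    "DFTInterpolator",
    "ConvolutionalEqualizer",
]

def _vector(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sequence")
    return arr


def dft_forward(x) -> np.ndarray:
    """Forward DFT, phi_k = sum_n x_n exp(-j 2 pi (k-1)(n-1) / N)."""
    return np.fft.fft(_vector(x))


def dft_inverse(phi) -> np.ndarray:
    """Inverse DFT with the 1/M factor; complex output."""
    phi = np.asarray(phi, dtype=complex).ravel()
    if phi.size == 0:
        raise ValueError("empty spectrum")
    return np.fft.ifft(phi)


def spectrum_zero_pad(phi, M: int) -> np.ndarray:
    """Insert M - N zeros between the two halves of an N-point spectrum.

    Even N: first N/2 coefficients, zeros, last N/2 coefficients.
    Odd N: first (N+1)/2 coefficients, zeros, last (N-1)/2 coefficients.

    Raises ``ValueError`` when M < N (decimation is unsupported).
    """
    phi = np.asarray(phi, dtype=complex).ravel()
    n = phi.size
    if n == 0:
        raise ValueError("empty spectrum")
    M = int(M)
    if M < n:
        raise ValueError(
            f"target length {M} < input length {n}: decimation unsupported")
    head = (n + 1) // 2  # == n/2 for even n, (n+1)/2 for odd n
    out = np.zeros(M, dtype=complex)
    out[:head] = phi[:head]
    if n - head:
        out[M - (n - head):] = phi[head:]
    return out


def dft_interpolate(x, M: int) -> np.ndarray:
    """Upsample ``x`` to length M by frequency-domain zero padding.

    Output is real valued: the imaginary part of the inverse transform is
    discarded.  For odd N the padded spectrum keeps exact conjugate
    symmetry and the residue is at rounding level; for even N the literal
    half-and-half split moves the whole Nyquist bin to the back half, so
    inputs with appreciable Nyquist content leave a small genuine residue.
    A warning is emitted when it exceeds 10 % of the signal amplitude.
    """
    xv = _vector(x)
    phi = spectrum_zero_pad(np.fft.fft(xv), M)
    z = np.fft.ifft(phi)
    resid = float(np.max(np.abs(z.imag)))
    scale = float(np.max(np.abs(xv)))
    if scale > 0 and resid > 0.1 * scale:
        warnings.warn(
            f"imaginary residue {resid:.3g} from half-spectrum zero padding "
            "is not negligible (high Nyquist content)", RuntimeWarning,
            stacklevel=2)
    return z.real


def convolutional_equalize(x, M: int) -> np.ndarray:
    """Stretch ``x`` to length M by full convolution with a moving-average kernel.

    The kernel has Q = M - N + 1 equal taps of value 1/Q (unit DC gain), so
    the full convolution output has length N + Q - 1 = M.
    """
    xv = _vector(x)
    q = int(M) - xv.size + 1
    if q < 1:
        raise ValueError(
            f"target length {M} < input length {xv.size}: kernel length "
            f"Q = {q} <= 0")
    kernel = np.full(q, 1.0 / q)
    return np.convolve(xv, kernel, mode="full")


def normalize_unit_interval(z) -> np.ndarray:
    """Affine map of a sequence onto [0, 1]; a constant sequence maps to 0.5."""
    zv = _vector(z)
    lo, hi = float(zv.min()), float(zv.max())
    if hi == lo:
        return np.full_like(zv, 0.5)
    return (zv - lo) / (hi - lo)


_METHODS = {
    "dft": dft_interpolate,
    "conv": convolutional_equalize,
    "convolution": convolutional_equalize,
}


def equalize(x, M: int, method: str = "dft", normalize: bool = True) -> np.ndarray:
    """Equalize one sequence to length M with the named method.

    Parameters
    ----------
    x : array-like or MotionSequence
    M : int
        Target length, must be >= len(x).
    method : {'dft', 'conv'}
    normalize : bool, default True
        Min-max normalize the output onto [0, 1].
    """
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown equalization method {method!r}") from None
    out = fn(x, M)
    if normalize:
        out = normalize_unit_interval(out)
    return out


class _BaseEqualizer(TransformerMixin, BaseEstimator):
    """Shared fit/transform scaffolding for the two equalizers."""

    _method: str

    def __init__(self, target_length=None, normalize=True):
        self.target_length = target_length
        self.normalize = normalize

    @staticmethod
    def _lengths(X):
        return [len(np.asarray(x).ravel()) for x in X]

    def fit(self, X, y=None):
        """Resolve the output length from ``target_length`` or the data.

        When ``target_length`` is None the longest training sequence sets
        the common length.
        """
        lengths = self._lengths(X)
        if not lengths:
            raise ValueError("empty training set")
        if self.target_length is None:
            self.target_length_ = max(lengths)
        else:
            self.target_length_ = int(self.target_length)
            if self.target_length_ < max(lengths):
                raise ValueError(
                    f"target_length {self.target_length_} is shorter than the "
                    f"longest input ({max(lengths)})")
        self.n_features_out_ = self.target_length_
        return self

    def transform(self, X):
        if not hasattr(self, "target_length_"):
            raise AttributeError("equalizer is not fitted")
        rows = [equalize(x, self.target_length_, method=self._method,
                         normalize=self.normalize) for x in X]
        return np.vstack(rows) if rows else np.empty((0, self.target_length_))


class DFTInterpolator(_BaseEqualizer):
    """Frequency-domain zero-padding upsampler as a sklearn transformer.

    Parameters
    ----------
    target_length : int or None
        Common output length M; None means the longest sequence seen in
        ``fit``.
    normalize : bool, default True
        Min-max normalize each output onto [0, 1].
    """

    _method = "dft"


class ConvolutionalEqualizer(_BaseEqualizer):
    """Moving-average (impulse-train kernel) stretcher as a sklearn transformer.

    The kernel length adapts per sequence: Q = M - N + 1 equal taps of 1/Q.
    """

    _method = "conv"
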