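"""Three-layer back-propagation network baseline.

The comparison method: a fully connected feed-forward network with one
hidden layer of 5 logistic units and one logistic output unit per category,
trained by full-batch gradient descent (the delta rule) on the sum of
squared output errors.  It consumes fixed-length inputs, which is why the
length equalizers exist; cascading an equalizer in front of this network is
the two-stage alternative to direct DTW template matching.

Everything here is written from first principles — forward pass, analytic
gradients, the training loop — so the gradient can be verified against
central finite differences in the tests.

Unspecified details resolved as package choices: logistic sigmoid on both
layers, error function E = 1/2 * sum of squared output errors (its RMSE is
the convergence criterion), batch updates with a fixed learning rate and no
momentum, initial weights uniform in [-0.5, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = ["NetworkWeights", "init_network", "forward_pass", "rmse",
           "train_backprop", "predict_label", "BackpropClassifier"]

N_HIDDEN = 5


@dataclass
class NetworkWeights:
    """Weights and biases of the 3-layer network.

    ``w1`` is (M, 5), ``b1`` is (5,), ``w2`` is (5, n_out), ``b2`` is
    (n_out,).  A unit computes g(sum_j w_j i_j - theta) with g the logistic
    sigmoid, so the biases enter with a minus sign.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    @property
    def input_length(self):
        return self.w1.shape[0]

    @property
    def output_count(self):
        return self.w2.shape[1]


def _sigmoid(a):
    return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))


def init_network(input_length: int, output_count: int, seed=None) -> NetworkWeights:
    """Random weights uniform in [-0.5, 0.5], reproducible under ``seed``."""
    if input_length < 1 or output_count < 1:
        raise ValueError("input_length and output_count must be >= 1")
    rng = np.random.default_rng(seed)
    return NetworkWeights(
        w1=rng.uniform(-0.5, 0.5, (input_length, N_HIDDEN)),
        b1=rng.uniform(-0.5, 0.5, N_HIDDEN),
        w2=rng.uniform(-0.5, 0.5, (N_HIDDEN, output_count)),
        b2=rng.uniform(-0.5, 0.5, output_count),
    )


def forward_pass(z, weights: NetworkWeights):
    """Output activations for one equalized input vector; all in (0, 1)."""
    zv = np.asarray(z, dtype=float).ravel()
    if zv.size != weights.input_length:
        raise ValueError(
            f"input length {zv.size} != configured {weights.input_length}")
    hidden = _sigmoid(zv @ weights.w1 - weights.b1)
    return _sigmoid(hidden @ weights.w2 - weights.b2)


def _forward_batch(X, weights):
    hidden = _sigmoid(X @ weights.w1 - weights.b1)
    out = _sigmoid(hidden @ weights.w2 - weights.b2)
    return hidden, out


def rmse(predictions, targets) -> float:
    """Root mean square componentwise error between two equal-shape arrays."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def gradients(X, T, weights: NetworkWeights):
    """Analytic gradients of E = 1/2 sum (out - T)^2 w.r.t. all parameters.

    Returns (dw1, db1, dw2, db2).  Biases enter as minus theta, so their
    gradients carry the opposite sign of a plain bias term.
    """
    hidden, out = _forward_batch(X, weights)
    d_out = (out - T) * out * (1.0 - out)          # (n, n_out)
    d_hid = (d_out @ weights.w2.T) * hidden * (1.0 - hidden)
    dw2 = hidden.T @ d_out
    db2 = -d_out.sum(axis=0)
    dw1 = X.T @ d_hid
    db1 = -d_hid.sum(axis=0)
    return dw1, db1, dw2, db2


def loss(X, T, weights: NetworkWeights) -> float:
    """E = 1/2 * sum of squared output errors over the batch."""
    _, out = _forward_batch(X, weights)
    return 0.5 * float(np.sum((out - T) ** 2))


def train_backprop(X, T, learning_rate=0.5, max_epochs=1000,
                   rmse_tolerance=0.05, seed=None, weights=None):
    """Full-batch delta-rule training until the RMSE tolerance or epoch cap.

    Parameters
    ----------
    X : (n, M) array of equalized inputs.
    T : (n, n_out) array of one-hot targets.
    learning_rate : float in (0, 1), exclusive on both ends.
    max_epochs : int
    rmse_tolerance : float
        Stop when the output RMSE drops below this.
    seed : int, optional
        Weight initialization seed (ignored if ``weights`` given).
    weights : NetworkWeights, optional
        Warm start.

    Returns
    -------
    (NetworkWeights, list of float)
        Final weights and the per-epoch RMSE trajectory.
    """
    if not 0.0 < learning_rate < 1.0:
        raise ValueError("learning_rate must lie strictly in (0, 1)")
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.ndim != 2 or T.ndim != 2 or X.shape[0] != T.shape[0]:
        raise ValueError("X and T must be 2-D with matching row counts")
    if weights is None:
        weights = init_network(X.shape[1], T.shape[1], seed=seed)
    elif weights.input_length != X.shape[1]:
        raise ValueError("warm-start weights do not match input length")
    trajectory = []
    for _ in range(int(max_epochs)):
        dw1, db1, dw2, db2 = gradients(X, T, weights)
        weights.w1 -= learning_rate * dw1
        weights.b1 -= learning_rate * db1
        weights.w2 -= learning_rate * dw2
        weights.b2 -= learning_rate * db2
        _, out = _forward_batch(X, weights)
        err = rmse(out, T)
        trajectory.append(err)
        if err < rmse_tolerance:
            break
    return weights, trajectory


def predict_label(z, weights: NetworkWeights, labels=None):
    """Label of the maximal output activation; ties go to the lowest code."""
    out = forward_pass(z, weights)
    idx = int(np.argmax(out))  # argmax returns the first (lowest) maximum
    return idx if labels is None else labels[idx]


class BackpropClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator around the from-scratch back-propagation net.

    Expects fixed-length inputs (run an equalizer first, or compose in a
    ``Pipeline`` with :class:`~motionwarp.equalize.DFTInterpolator` /
    :class:`~motionwarp.equalize.ConvolutionalEqualizer`).

    Parameters
    ----------
    learning_rate : float in (0, 1), default 0.5
    max_epochs : int, default 1000
    rmse_tolerance : float, default 0.05
    random_state : int, optional
    """

    def __init__(self, learning_rate=0.5, max_epochs=1000,
                 rmse_tolerance=0.05, random_state=None):
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.rmse_tolerance = rmse_tolerance
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array of equalized sequences")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self.weights_, self.rmse_trajectory_ = train_backprop(
            X, T, learning_rate=self.learning_rate,
            max_epochs=self.max_epochs, rmse_tolerance=self.rmse_tolerance,
            seed=self.random_state)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        _, out = _forward_batch(X, self.weights_)
        return out

    def predict(self, X):
        out = self.decision_function(X)
        return self.classes_[np.argmax(out, axis=1)]
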