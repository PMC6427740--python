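"""Three-layer feed-forward network trained by back-propagation.

Hidden unit j computes z_j = s(sum_i w_ij x_i - theta_j); the single output
unit computes y = s(sum_j w_j z_j - theta_0), with s the logistic sigmoid.
Thresholds enter with a minus sign (not as added biases).  The default
hidden width is round(sqrt(n)) — an n-unit hidden layer over tens of
thousands of indicators would be severely over-parameterized for fewer than
two thousand training tuples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import TrainingError, ValidationError
from .activations import sigmoid

__all__ = ["ShallowANN", "ann_forward", "ann_init", "ann_train_backprop"]


@dataclass
class ShallowANN:
    w_in: np.ndarray        # (n, m) input-to-hidden weights
    theta_hidden: np.ndarray  # (m,) hidden thresholds
    w_out: np.ndarray       # (m,) hidden-to-output weights
    theta_out: float        # output threshold

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]


def ann_init(n: int, m: int | None = None, rng: np.random.Generator | None = None
             ) -> ShallowANN:
    """Small random initialization; default hidden width m = round(sqrt(n))."""
    if rng is None:
        rng = np.random.default_rng(0)
    if m is None:
        m = max(1, round(np.sqrt(n)))
    scale = 1.0 / np.sqrt(n)
    return ShallowANN(
        w_in=rng.uniform(-scale, scale, size=(n, m)),
        theta_hidden=rng.uniform(-scale, scale, size=m),
        w_out=rng.uniform(-0.5, 0.5, size=m),
        theta_out=float(rng.uniform(-0.5, 0.5)),
    )


def _hidden(model: ShallowANN, X: np.ndarray) -> np.ndarray:
    return sigmoid(X @ model.w_in - model.theta_hidden)


def ann_forward(model: ShallowANN, X: np.ndarray) -> np.ndarray:
    """Forward pass; accepts a single vector or a (N, n) batch."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_inputs:
        raise ValidationError(
            f"input width {X.shape[1]} != network width {model.n_inputs}")
    Z = _hidden(model, X)
    y = sigmoid(Z @ model.w_out - model.theta_out)
    return float(y[0]) if single else y


def ann_gradients(model: ShallowANN, X: np.ndarray, y: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Gradients of the mean squared error over the batch w.r.t. all parameters."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    N = len(y)
    Z = _hidden(model, X)
    out = sigmoid(Z @ model.w_out - model.theta_out)
    # d(mean (out - y)^2)
    d_out = 2.0 * (out - y) / N * out * (1.0 - out)      # (N,)
    g_w_out = Z.T @ d_out                                 # (m,)
    g_theta_out = -float(d_out.sum())
    d_hidden = np.outer(d_out, model.w_out) * Z * (1.0 - Z)  # (N, m)
    g_w_in = X.T @ d_hidden                               # (n, m)
    g_theta_hidden = -d_hidden.sum(axis=0)
    return g_w_in, g_theta_hidden, g_w_out, g_theta_out


def ann_train_backprop(X: np.ndarray, y: np.ndarray, m: int | None = None,
                       epochs: int = 50, lr: float = 0.1, seed: int = 0,
                       batch_size: int = 16) -> ShallowANN:
    """Minibatch SGD on the squared-error objective; returns the epoch-best model.

    The model snapshot with the lowest training RMSE across epochs (including
    the initial state) is returned.  Deterministic for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValidationError("training set must be non-empty")
    rng = np.random.default_rng(seed)
    model = ann_init(X.shape[1], m, rng)

    def _rmse(mdl):
        r = ann_forward(mdl, X) - y
        return float(np.sqrt(np.mean(r * r)))

    def _copy(mdl):
        return ShallowANN(mdl.w_in.copy(), mdl.theta_hidden.copy(),
                          mdl.w_out.copy(), mdl.theta_out)

    best = _copy(model)
    best_rmse = _rmse(model)
    N = len(y)
    for _ in range(epochs):
        order = rng.permutation(N)
        for start in range(0, N, batch_size):
            idx = order[start:start + batch_size]
            gw, gth, gwo, gto = ann_gradients(model, X[idx], y[idx])
            if not (np.all(np.isfinite(gw)) and np.isfinite(gto)):
                raise TrainingError("non-finite gradient in backprop")
            model.w_in -= lr * gw
            model.theta_hidden -= lr * gth
            model.w_out -= lr * gwo
            model.theta_out -= lr * gto
        r = _rmse(model)
        if r < best_rmse:
            best_rmse = r
            best = _copy(model)
    return best
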