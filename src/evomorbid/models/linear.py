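"""Multiple linear regression with a ridge guard.

The prediction is y = a0 + a.x.  At study scale the feature dimension far
exceeds the number of training tuples, so plain normal equations are
singular; a tiny ridge (default 1e-8) on the coefficients (never on the
intercept) selects the minimum-norm least-squares solution deterministically.
When n > N the equivalent dual (kernel) form is solved instead, which is an
(N x N) system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ..errors import ValidationError

__all__ = ["MLRModel", "mlr_fit", "mlr_predict"]


@dataclass
class MLRModel:
    intercept: float
    coef: np.ndarray


def mlr_fit(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> MLRModel:
    """Least-squares fit of y = a0 + a.x with ridge guard on a (not a0)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValidationError("X must be 2-D with at least one feature")
    if len(X) != len(y) or len(y) == 0:
        raise ValidationError("X and y must be non-empty with equal length")
    N, n = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    if n <= N:
        A = Xc.T @ Xc + ridge * np.eye(n)
        coef = scipy.linalg.solve(A, Xc.T @ yc, assume_a="pos")
    else:
        K = Xc @ Xc.T + ridge * np.eye(N)
        coef = Xc.T @ scipy.linalg.solve(K, yc, assume_a="pos")
    intercept = y_mean - float(x_mean @ coef)
    return MLRModel(intercept=intercept, coef=coef)


def mlr_predict(model: MLRModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.coef):
        raise ValidationError(
            f"feature width {X.shape[1]} != model width {len(model.coef)}")
    return model.intercept + X @ model.coef
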