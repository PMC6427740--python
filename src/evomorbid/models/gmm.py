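"""Gaussian-mixture output head.

A K-component full-covariance Gaussian mixture is fitted by EM over the
joint vector (z, y) — the top-layer code z concatenated with the morbidity
target y.  Prediction is the conditional expectation under the fitted joint:

    yhat(z) = sum_k r_k(z) * m_k(z)

with responsibilities r_k(z) proportional to pi_k N(z; mu_k^z, S_k^zz) and
per-component linear-Gaussian regressors

    m_k(z) = mu_k^y + S_k^yz (S_k^zz)^{-1} (z - mu_k^z).

With K = 1 this reduces exactly to joint-Gaussian (linear) regression.  The
analytic gradient d yhat / d z is provided for back-propagating the squared
error through the encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from ..errors import ValidationError

__all__ = ["GMMHead", "gmm_fit_joint", "gmm_predict", "gmm_predict_grad"]

REG_COVAR = 1e-6


@dataclass
class GMMHead:
    """Fitted joint mixture over (z, y); y is the last coordinate."""

    weights: np.ndarray       # (K,)
    means: np.ndarray         # (K, d+1)
    covariances: np.ndarray   # (K, d+1, d+1)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    # cached conditional pieces, built lazily
    _cond: dict | None = None

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def code_dim(self) -> int:
        return self.means.shape[1] - 1

    def _conditional(self) -> dict:
        if self._cond is None:
            d = self.code_dim
            K = self.n_components
            mu_z = self.means[:, :d]
            mu_y = self.means[:, d]
            chos, A, logdet = [], np.empty((K, d)), np.empty(K)
            for k in range(K):
                S = self.covariances[k]
                S_zz = S[:d, :d]
                S_zy = S[:d, d]
                c, low = cho_factor(S_zz, lower=True)
                chos.append((c, low))
                A[k] = cho_solve((c, low), S_zy)
                logdet[k] = 2.0 * np.sum(np.log(np.diag(c)))
            self._cond = dict(mu_z=mu_z, mu_y=mu_y, chos=chos, A=A,
                              logdet=logdet, d=d)
        return self._cond


def gmm_fit_joint(Z: np.ndarray, y: np.ndarray, K: int = 3, seed: int = 0,
                  max_iter: int = 200, trace: bool = False) -> GMMHead:
    """EM fit of a K-component full-covariance mixture over (z, y).

    Covariance diagonals are regularized by 1e-6.  With ``trace`` the fit is
    stepped one EM iteration at a time and the per-iteration lower bound is
    recorded on the returned head.  Non-convergence returns the best-so-far
    parameters with ``converged=False``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(Z) != len(y):
        raise ValidationError("Z and y must have equal length")
    if K > len(y):
        raise ValidationError(f"K={K} exceeds sample count {len(y)}")
    if K < 1:
        raise ValidationError("K must be >= 1")
    joint = np.column_stack([Z, y])

    trace_vals: list[float] = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if trace:
            gm = GaussianMixture(n_components=K, covariance_type="full",
                                 reg_covar=REG_COVAR, random_state=seed,
                                 max_iter=1, warm_start=True, n_init=1,
                                 tol=0.0)
            prev = -np.inf
            for _ in range(max_iter):
                gm.fit(joint)
                trace_vals.append(float(gm.lower_bound_))
                if abs(gm.lower_bound_ - prev) < 1e-10:
                    break
                prev = gm.lower_bound_
            converged = bool(gm.converged_) or len(trace_vals) < max_iter
        else:
            gm = GaussianMixture(n_components=K, covariance_type="full",
                                 reg_covar=REG_COVAR, random_state=seed,
                                 max_iter=max_iter, n_init=1)
            gm.fit(joint)
            converged = bool(gm.converged_)
    if not converged:
        warnings.warn("GMM head EM did not converge; returning best-so-far",
                      RuntimeWarning, stacklevel=2)
    return GMMHead(weights=gm.weights_.copy(), means=gm.means_.copy(),
                   covariances=gm.covariances_.copy(),
                   loglik_trace=trace_vals, converged=converged)


def _responsibilities(head: GMMHead, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Responsibilities r_k(z) and whitened residuals info for the gradient."""
    cond = head._conditional()
    d = cond["d"]
    N = len(Z)
    K = head.n_components
    log_r = np.empty((N, K))
    for k in range(K):
        diff = Z - cond["mu_z"][k]
        sol = cho_solve(cond["chos"][k], diff.T).T       # (N, d) = S_zz^-1 diff
        maha = np.sum(diff * sol, axis=1)
        log_r[:, k] = (np.log(head.weights[k]) - 0.5 * maha
                       - 0.5 * cond["logdet"][k] - 0.5 * d * np.log(2 * np.pi))
    log_r -= log_r.max(axis=1, keepdims=True)
    r = np.exp(log_r)
    r /= r.sum(axis=1, keepdims=True)
    return r, log_r


def gmm_predict(head: GMMHead, Z: np.ndarray) -> np.ndarray:
    """Conditional expectation E[y | z] under the fitted joint mixture."""
    Z = np.asarray(Z, dtype=float)
    single = Z.ndim == 1
    Z = np.atleast_2d(Z)
    if Z.shape[1] != head.code_dim:
        raise ValidationError(
            f"code width {Z.shape[1]} != head width {head.code_dim}")
    cond = head._conditional()
    r, _ = _responsibilities(head, Z)
    m = np.empty_like(r)
    for k in range(head.n_components):
        m[:, k] = cond["mu_y"][k] + (Z - cond["mu_z"][k]) @ cond["A"][k]
    out = np.sum(r * m, axis=1)
    return float(out[0]) if single else out


def gmm_predict_grad(head: GMMHead, Z: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(yhat, d yhat / d z) for a batch of codes; gradient shape (N, d).

    Uses d r_k / d z = r_k (g_k - sum_j r_j g_j) with
    g_k = -(S_zz^k)^{-1} (z - mu_z^k), and d m_k / d z = A_k.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    cond = head._conditional()
    K = head.n_components
    N, d = Z.shape
    r, _ = _responsibilities(head, Z)
    m = np.empty((N, K))
    g = np.empty((N, K, d))
    for k in range(K):
        diff = Z - cond["mu_z"][k]
        m[:, k] = cond["mu_y"][k] + diff @ cond["A"][k]
        g[:, k, :] = -cho_solve(cond["chos"][k], diff.T).T
    yhat = np.sum(r * m, axis=1)
    g_bar = np.einsum("nk,nkd->nd", r, g)
    dr = r[:, :, None] * (g - g_bar[:, None, :])          # (N, K, d)
    grad = np.einsum("nkd,nk->nd", dr, m) + np.einsum("nk,kd->nd", r, cond["A"])
    return yhat, grad
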