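"""Restricted Boltzmann machine layers.

A two-layer energy-based model over a visible vector x and a binary hidden
vector z.  For Bernoulli visibles the energy is

    E(x, z) = -b.x - c.z - x.W z

and for Gaussian visibles (the bottom layer of a stack over standardized
real inputs, unit variances)

    E(x, z) = sum_i (x_i - b_i)^2 / 2 - c.z - x.W z.

Training uses one-step contrastive divergence (CD-1): sample hidden given
visible, reconstruct the visible layer, recompute hidden probabilities, and
apply the positive-minus-negative statistics as the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from .activations import sigmoid

__all__ = ["RBMLayer", "rbm_energy", "rbm_cd_step", "rbm_init", "rbm_encode"]


@dataclass
class RBMLayer:
    b: np.ndarray              # (nv,) visible bias
    c: np.ndarray              # (nh,) hidden bias
    w: np.ndarray              # (nv, nh) weights
    visible_kind: str = "bernoulli"   # "bernoulli" | "gaussian"

    def __post_init__(self):
        nv, nh = self.w.shape
        if self.b.shape != (nv,) or self.c.shape != (nh,):
            raise ValidationError("RBM bias/weight dimensions inconsistent")
        if self.visible_kind not in ("bernoulli", "gaussian"):
            raise ValidationError(f"unknown visible_kind {self.visible_kind!r}")

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]


def rbm_init(nv: int, nh: int, visible_kind: str = "bernoulli",
             rng: np.random.Generator | None = None) -> RBMLayer:
    if rng is None:
        rng = np.random.default_rng(0)
    return RBMLayer(
        b=np.zeros(nv),
        c=np.zeros(nh),
        w=rng.normal(0.0, 0.01, size=(nv, nh)),
        visible_kind=visible_kind,
    )


def rbm_energy(layer: RBMLayer, x: np.ndarray, z: np.ndarray) -> float:
    """Joint energy E(x, z); lower energy = higher probability."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != (layer.n_visible,) or z.shape != (layer.n_hidden,):
        raise ValidationError("x/z dimensions do not match the layer")
    interaction = -float(x @ layer.w @ z) - float(layer.c @ z)
    if layer.visible_kind == "gaussian":
        return float(np.sum((x - layer.b) ** 2) / 2.0) + interaction
    return -float(layer.b @ x) + interaction


def rbm_hidden_probs(layer: RBMLayer, X: np.ndarray) -> np.ndarray:
    """P(z_j = 1 | x) = s(c_j + x.W_:j); valid for both visible kinds (unit var)."""
    return sigmoid(X @ layer.w + layer.c)


def rbm_encode(layer: RBMLayer, X: np.ndarray) -> np.ndarray:
    """Deterministic (mean-field) hidden activations, used for stacking."""
    return rbm_hidden_probs(layer, np.atleast_2d(np.asarray(X, dtype=float)))


def _visible_from_hidden(layer: RBMLayer, H: np.ndarray) -> np.ndarray:
    mean = H @ layer.w.T + layer.b
    if layer.visible_kind == "gaussian":
        return mean          # conditional mean, unit variance
    return sigmoid(mean)     # Bernoulli probabilities


def rbm_reconstruction_error(layer: RBMLayer, batch: np.ndarray) -> float:
    """Mean squared one-step reconstruction error using mean-field passes."""
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    H = rbm_hidden_probs(layer, X)
    V = _visible_from_hidden(layer, H)
    return float(np.mean(np.sum((X - V) ** 2, axis=1)))


def rbm_cd_step(layer: RBMLayer, batch: np.ndarray, lr: float,
                rng: np.random.Generator) -> tuple[RBMLayer, float]:
    """One CD-1 update on a batch (in place); returns (layer, reconstruction error).

    Recipe: h ~ Bernoulli(P(z|x)); visible reconstruction v' is the
    conditional mean given h (probabilities for Bernoulli visibles, the
    Gaussian mean for Gaussian visibles); h' = P(z|v') (probabilities, not
    resampled).  Updates:

        W += lr * (x'h_p - v''h'_p) / B,  b += lr * mean(x - v'),
        c += lr * mean(h_p - h'_p)

    where h_p, h'_p are hidden probabilities.  The returned error is the mean
    squared distance between x and v'.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    B = len(X)
    h_p = rbm_hidden_probs(layer, X)
    h_sample = (rng.random(h_p.shape) < h_p).astype(float)
    v_recon = _visible_from_hidden(layer, h_sample)
    h_p2 = rbm_hidden_probs(layer, v_recon)

    err = float(np.mean(np.sum((X - v_recon) ** 2, axis=1)))
    if lr != 0.0:
        layer.w += lr * (X.T @ h_p - v_recon.T @ h_p2) / B
        layer.b += lr * np.mean(X - v_recon, axis=0)
        layer.c += lr * np.mean(h_p - h_p2, axis=0)
    return layer, err
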