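"""(Denoising) autoencoder layers.

Encode z = s(Wx + b), decode x' = s(W'z + b').  The denoising variant first
corrupts the input by masking random components to zero (rate rho) and is
trained to reconstruct the *clean* input from the corrupted one; the loss is
always measured against the clean x:

    L = mean over batch of ||x - x'||^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from .activations import sigmoid

__all__ = ["AutoencoderLayer", "ae_encode", "ae_decode",
           "ae_reconstruction_loss", "ae_grad_step", "ae_init", "corrupt_input"]


@dataclass
class AutoencoderLayer:
    w: np.ndarray              # (nv, nh) encode weights
    b: np.ndarray              # (nh,) encode bias
    w_dec: np.ndarray          # (nh, nv) decode weights
    b_dec: np.ndarray          # (nv,) decode bias
    corruption_rate: float = 0.0

    def __post_init__(self):
        nv, nh = self.w.shape
        if self.w_dec.shape != (nh, nv) or self.b.shape != (nh,) or self.b_dec.shape != (nv,):
            raise ValidationError("autoencoder dimensions inconsistent")
        if not 0.0 <= self.corruption_rate < 1.0:
            raise ValidationError("corruption_rate must be in [0, 1)")

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]


def ae_init(nv: int, nh: int, corruption_rate: float = 0.0,
            rng: np.random.Generator | None = None) -> AutoencoderLayer:
    if rng is None:
        rng = np.random.default_rng(0)
    scale = 1.0 / np.sqrt(nv)
    return AutoencoderLayer(
        w=rng.uniform(-scale, scale, size=(nv, nh)),
        b=np.zeros(nh),
        w_dec=rng.uniform(-scale, scale, size=(nh, nv)),
        b_dec=np.zeros(nv),
        corruption_rate=corruption_rate,
    )


def ae_encode(layer: AutoencoderLayer, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != layer.n_visible:
        raise ValidationError(
            f"input width {X.shape[-1]} != layer width {layer.n_visible}")
    return sigmoid(X @ layer.w + layer.b)


def ae_decode(layer: AutoencoderLayer, Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.shape[-1] != layer.n_hidden:
        raise ValidationError(
            f"code width {Z.shape[-1]} != layer hidden size {layer.n_hidden}")
    return sigmoid(Z @ layer.w_dec + layer.b_dec)


def corrupt_input(x: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: each component is zeroed independently with probability rho.

    rho = 0 is the identity and consumes no random draws (a plain autoencoder
    and a denoising one at rho = 0 follow bit-identical code paths).
    """
    if not 0.0 <= rho < 1.0:
        raise ValidationError("corruption rate must be in [0, 1)")
    x = np.asarray(x, dtype=float)
    if rho == 0.0:
        return x
    keep = rng.random(x.shape) >= rho
    return x * keep


def ae_reconstruction_loss(layer: AutoencoderLayer, batch: np.ndarray,
                           rng: np.random.Generator | None = None,
                           corruption_mask: np.ndarray | None = None) -> float:
    """Mean squared reconstruction error against the *clean* batch.

    Corruption (if the layer has rho > 0) is applied to the encoder input
    only; either pass an rng to draw a fresh mask or a fixed boolean
    ``corruption_mask`` (True = keep) for deterministic evaluation.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    if len(X) == 0:
        raise ValidationError("batch must be non-empty")
    X_in = X
    if corruption_mask is not None:
        X_in = X * corruption_mask
    elif layer.corruption_rate > 0.0:
        if rng is None:
            raise ValidationError("corrupting loss needs an rng or a fixed mask")
        X_in = corrupt_input(X, layer.corruption_rate, rng)
    X_rec = ae_decode(layer, ae_encode(layer, X_in))
    return float(np.mean(np.sum((X - X_rec) ** 2, axis=1)))


def ae_grad_step(layer: AutoencoderLayer, batch: np.ndarray, lr: float,
                 rng: np.random.Generator) -> tuple[AutoencoderLayer, float]:
    """One full-batch gradient step on the reconstruction loss (in place).

    Returns (layer, loss before the step).  For denoising layers a fresh
    corruption mask is drawn per call.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    B = len(X)
    X_in = corrupt_input(X, layer.corruption_rate, rng)
    Z = sigmoid(X_in @ layer.w + layer.b)
    X_rec = sigmoid(Z @ layer.w_dec + layer.b_dec)
    diff = X_rec - X                                     # (B, nv)
    loss = float(np.mean(np.sum(diff * diff, axis=1)))

    if lr != 0.0:
        d_rec = 2.0 * diff / B * X_rec * (1.0 - X_rec)   # (B, nv)
        g_w_dec = Z.T @ d_rec
        g_b_dec = d_rec.sum(axis=0)
        d_z = (d_rec @ layer.w_dec.T) * Z * (1.0 - Z)    # (B, nh)
        g_w = X_in.T @ d_z
        g_b = d_z.sum(axis=0)
        layer.w -= lr * g_w
        layer.b -= lr * g_b
        layer.w_dec -= lr * g_w_dec
        layer.b_dec -= lr * g_b_dec
    return layer, loss
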