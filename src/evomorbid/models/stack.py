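"""Deep stacks and flat parameter-vector codecs.

A DeepStack is an ordered list of RBM layers (kind "DBN") or autoencoder
layers (kinds "DAE"/"DDAE") whose sizes chain: layer l's visible size equals
layer l-1's hidden size.  Encoding propagates deterministic sigmoid
activations layer by layer; that encoder chain (layer weights + hidden
biases) is the prediction path feeding the Gaussian-mixture output head.

The flatten/restore codecs map models to/from flat real vectors in a fixed,
documented order — the interface the evolutionary optimizer works in.  Two
codecs exist: the full codec covers every parameter (used for layerwise
pretraining of a single layer); the encoder codec covers only parameters on
the prediction path (used for whole-network fine-tuning).

Flattening order (C order within each array):
  MLR:  [intercept, coef]
  ANN:  [w_in, theta_hidden, w_out, theta_out]
  RBM layer, full:  [b, c, w]          encoder part: [c, w]
  AE layer, full:   [w, b, w_dec, b_dec]   encoder part: [w, b]
  stacks: layer 0 first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from .ann import ShallowANN
from .autoencoder import AutoencoderLayer, ae_encode
from .linear import MLRModel
from .rbm import RBMLayer, rbm_encode, rbm_init
from .autoencoder import ae_init

__all__ = ["DeepStack", "init_stack", "stack_encode",
           "flatten_params", "restore_params", "param_count",
           "flatten_encoder", "restore_encoder", "encoder_param_count"]

STACK_KINDS = ("DBN", "DAE", "DDAE")


@dataclass
class DeepStack:
    kind: str                      # "DBN" | "DAE" | "DDAE"
    layers: list                   # RBMLayer or AutoencoderLayer
    hidden_sizes: tuple[int, ...]

    def __post_init__(self):
        if self.kind not in STACK_KINDS:
            raise ValidationError(f"unknown stack kind {self.kind!r}")
        if len(self.layers) != len(self.hidden_sizes):
            raise ValidationError("hidden_sizes must match layer list")
        for i, layer in enumerate(self.layers):
            if layer.n_hidden != self.hidden_sizes[i]:
                raise ValidationError(f"layer {i} hidden size mismatch")
            if i > 0 and layer.n_visible != self.hidden_sizes[i - 1]:
                raise ValidationError(f"layer {i} does not chain onto layer {i - 1}")

    @property
    def n_inputs(self) -> int:
        return self.layers[0].n_visible

    @property
    def code_dim(self) -> int:
        return self.hidden_sizes[-1]


def init_stack(kind: str, n_inputs: int, hidden_sizes: tuple[int, ...],
               corruption_rate: float = 0.2,
               rng: np.random.Generator | None = None) -> DeepStack:
    """Random stack; bottom RBM layer is Gaussian-visible, upper ones Bernoulli.

    ``corruption_rate`` applies to every layer of a DDAE and is forced to 0
    for DAE; it is ignored for DBN.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not hidden_sizes:
        raise ValidationError("need at least one hidden layer")
    sizes = (n_inputs,) + tuple(hidden_sizes)
    layers = []
    for i in range(len(hidden_sizes)):
        nv, nh = sizes[i], sizes[i + 1]
        if kind == "DBN":
            layers.append(rbm_init(nv, nh,
                                   visible_kind="gaussian" if i == 0 else "bernoulli",
                                   rng=rng))
        else:
            rho = corruption_rate if kind == "DDAE" else 0.0
            layers.append(ae_init(nv, nh, corruption_rate=rho, rng=rng))
    return DeepStack(kind=kind, layers=layers, hidden_sizes=tuple(hidden_sizes))


def stack_encode(stack: DeepStack, X: np.ndarray, upto: int | None = None
                 ) -> np.ndarray:
    """Deterministic encoder chain; ``upto`` stops after that many layers."""
    H = np.atleast_2d(np.asarray(X, dtype=float))
    layers = stack.layers if upto is None else stack.layers[:upto]
    for layer in layers:
        if isinstance(layer, RBMLayer):
            H = rbm_encode(layer, H)
        else:
            H = ae_encode(layer, H)
    return H


# ---------------------------------------------------------------------------
# codecs
# ---------------------------------------------------------------------------

def _layer_arrays_full(layer) -> list[np.ndarray]:
    if isinstance(layer, RBMLayer):
        return [layer.b, layer.c, layer.w]
    return [layer.w, layer.b, layer.w_dec, layer.b_dec]


def _layer_arrays_encoder(layer) -> list[np.ndarray]:
    if isinstance(layer, RBMLayer):
        return [layer.c, layer.w]
    return [layer.w, layer.b]


def _model_arrays(model) -> list[np.ndarray]:
    if isinstance(model, MLRModel):
        return [np.atleast_1d(np.asarray(model.intercept, dtype=float)), model.coef]
    if isinstance(model, ShallowANN):
        return [model.w_in, model.theta_hidden, model.w_out,
                np.atleast_1d(np.asarray(model.theta_out, dtype=float))]
    if isinstance(model, (RBMLayer, AutoencoderLayer)):
        return _layer_arrays_full(model)
    if isinstance(model, DeepStack):
        out = []
        for layer in model.layers:
            out.extend(_layer_arrays_full(layer))
        return out
    raise ValidationError(f"cannot flatten object of type {type(model).__name__}")


def flatten_params(model) -> np.ndarray:
    """Flatten a model's parameters into one real vector (order-stable)."""
    return np.concatenate([np.ravel(a) for a in _model_arrays(model)])


def param_count(model) -> int:
    return sum(a.size for a in _model_arrays(model))


def _fill_arrays(arrays: list[np.ndarray], vector: np.ndarray) -> None:
    total = sum(a.size for a in arrays)
    if vector.shape != (total,):
        raise ValidationError(
            f"parameter vector length {vector.shape} != expected ({total},)")
    pos = 0
    for a in arrays:
        a[...] = vector[pos:pos + a.size].reshape(a.shape)
        pos += a.size


def _clone(model):
    if isinstance(model, MLRModel):
        return MLRModel(model.intercept, model.coef.copy())
    if isinstance(model, ShallowANN):
        return ShallowANN(model.w_in.copy(), model.theta_hidden.copy(),
                          model.w_out.copy(), model.theta_out)
    if isinstance(model, RBMLayer):
        return RBMLayer(model.b.copy(), model.c.copy(), model.w.copy(),
                        model.visible_kind)
    if isinstance(model, AutoencoderLayer):
        return AutoencoderLayer(model.w.copy(), model.b.copy(),
                                model.w_dec.copy(), model.b_dec.copy(),
                                model.corruption_rate)
    if isinstance(model, DeepStack):
        return DeepStack(model.kind, [_clone(l) for l in model.layers],
                         model.hidden_sizes)
    raise ValidationError(f"cannot clone object of type {type(model).__name__}")


def restore_params(template, vector: np.ndarray):
    """Inverse of flatten_params: a new model shaped like ``template``."""
    vector = np.asarray(vector, dtype=float)
    model = _clone(template)
    if isinstance(model, MLRModel):
        scalar_box = np.empty(1)
        _fill_arrays([scalar_box, model.coef], vector)
        model.intercept = float(scalar_box[0])
        return model
    if isinstance(model, ShallowANN):
        scalar_box = np.empty(1)
        _fill_arrays([model.w_in, model.theta_hidden, model.w_out, scalar_box],
                     vector)
        model.theta_out = float(scalar_box[0])
        return model
    _fill_arrays(_model_arrays(model), vector)
    return model


def flatten_encoder(stack: DeepStack) -> np.ndarray:
    """Flatten only the prediction-path parameters (layer weights + hidden biases)."""
    arrays = []
    for layer in stack.layers:
        arrays.extend(_layer_arrays_encoder(layer))
    return np.concatenate([np.ravel(a) for a in arrays])


def encoder_param_count(stack: DeepStack) -> int:
    return sum(a.size for layer in stack.layers
               for a in _layer_arrays_encoder(layer))


def restore_encoder(template: DeepStack, vector: np.ndarray) -> DeepStack:
    """New stack with encoder parameters from ``vector``; the rest copied."""
    vector = np.asarray(vector, dtype=float)
    stack = _clone(template)
    arrays = []
    for layer in stack.layers:
        arrays.extend(_layer_arrays_encoder(layer))
    _fill_arrays(arrays, vector)
    return stack
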