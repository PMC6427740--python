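"""Training regimes for the eight model kinds.

Shallow kinds:  MLR (ridge-guarded least squares) and ANN (back-propagation).
Deep kinds:     DBN / DAE / DDAE — greedy layerwise unsupervised pretraining
                followed by supervised fine-tuning of the whole encoder
                against the RMSE objective, with a Gaussian-mixture output
                head mapping top-layer codes to morbidity.
Evo kinds:      EvoDBN / EvoDAE / EvoDDAE — the same two stages, but both
                driven by water wave optimization instead of gradients:
                layerwise WWO maximizing negative reconstruction error, then
                whole-encoder WWO maximizing 1/(RMSE + 1e-12).

Fine-tuning (either regime) optimizes the encoder-affecting parameters only
(layer weights and hidden biases); RBM visible biases and autoencoder
decoders do not enter the prediction path.  One initial wave of the
fine-tuning WWO population is seeded from the pretrained parameters, and the
final model is the better of {best wave, pretrained baseline} under a
freshly refitted head — so evolutionary fine-tuning can never degrade
training fitness relative to its initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import TrainingError, ValidationError
from .models import (
    DeepStack, GMMHead, MLRModel, ShallowANN,
    ae_grad_step, ae_reconstruction_loss, ann_forward, ann_train_backprop,
    flatten_encoder, flatten_params, gmm_fit_joint, gmm_predict,
    gmm_predict_grad, init_stack, mlr_fit, mlr_predict, restore_encoder,
    restore_params, stack_encode,
)
from .models.rbm import RBMLayer, rbm_cd_step, rbm_reconstruction_error
from .wwo import WWOConfig, optimize

__all__ = ["TrainSpec", "MODEL_KINDS", "train_model",
           "pretrain_gradient", "finetune_gradient",
           "pretrain_evolutionary", "finetune_evolutionary",
           "MLRPredictor", "ANNPredictor", "DeepPredictor"]

MODEL_KINDS = ("MLR", "ANN", "DBN", "EvoDBN", "DAE", "EvoDAE", "DDAE", "EvoDDAE")


@dataclass(frozen=True)
class TrainSpec:
    """Hyperparameters for one training run.

    ``hidden_sizes`` are the stack widths (study scale used four layers such
    as 3860/550/80/12 for the DBN and 4500/640/80/12 for DAE/DDAE; the
    desk-scale default here is much smaller).  ``weight_bounds`` is the
    per-parameter search box for evolutionary training — after input
    standardization, [-4, 4] covers the useful sigmoid operating range.
    """

    model_kind: str = "MLR"
    hidden_sizes: tuple[int, ...] = (60, 24, 8, 4)
    # gradient budgets
    epochs: int = 25                   # layerwise pretraining epochs per layer
    lr: float = 0.1
    batch_size: int = 16
    finetune_epochs: int = 30
    finetune_lr: float = 0.05
    head_refresh: int = 5              # refit the GMM head every this many epochs
    # output head
    gmm_k: int = 3
    # denoising
    corruption: float = 0.2
    # evolutionary budgets
    weight_bounds: tuple[float, float] = (-4.0, 4.0)
    wwo_population: int = 8
    wwo_pretrain_budget: int = 400     # objective evaluations per layer
    wwo_finetune_budget: int = 300
    wwo_alpha: float = 1.0026
    wwo_lambda_init: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {self.model_kind!r}")
        lo, hi = self.weight_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValidationError("weight_bounds must be a finite interval")


def _sub_seed(seed: int, tag: int) -> int:
    return int((seed * 1_000_003 + tag) % (2**31 - 1))


def _rmse(pred: np.ndarray, y: np.ndarray) -> float:
    r = np.asarray(pred) - np.asarray(y)
    return float(np.sqrt(np.mean(r * r)))


# ---------------------------------------------------------------------------
# predictors: the uniform predict(x) -> morbidity contract
# ---------------------------------------------------------------------------

class MLRPredictor:
    def __init__(self, model: MLRModel):
        self.model = model

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(mlr_predict(self.model, X), 0.0, 1.0)

    def parameters(self) -> np.ndarray:
        return flatten_params(self.model)


class ANNPredictor:
    def __init__(self, model: ShallowANN):
        self.model = model

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(ann_forward(self.model, np.atleast_2d(X)), 0.0, 1.0)

    def parameters(self) -> np.ndarray:
        return flatten_params(self.model)


class DeepPredictor:
    def __init__(self, stack: DeepStack, head: GMMHead):
        self.stack = stack
        self.head = head

    def predict(self, X: np.ndarray) -> np.ndarray:
        codes = stack_encode(self.stack, X)
        return np.clip(gmm_predict(self.head, codes), 0.0, 1.0)

    def parameters(self) -> np.ndarray:
        return flatten_params(self.stack)


# ---------------------------------------------------------------------------
# stage 1: layerwise pretraining
# ---------------------------------------------------------------------------

def pretrain_gradient(stack: DeepStack, X: np.ndarray, spec: TrainSpec
                      ) -> tuple[DeepStack, list[list[float]]]:
    """Greedy layerwise pretraining: CD-1 for RBMs, gradient descent for AEs.

    Layer 1 trains on the (standardized) data; each later layer trains on the
    previous layer's deterministic codes — later layers never see raw
    features.  Returns (stack, per-layer loss history).  Zero epochs leaves
    the stack unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    histories: list[list[float]] = []
    H = X
    for li, layer in enumerate(stack.layers):
        rng = np.random.default_rng(_sub_seed(spec.seed, 10 + li))
        hist: list[float] = []
        for _ in range(spec.epochs):
            order = rng.permutation(len(H))
            epoch_losses = []
            for start in range(0, len(H), spec.batch_size):
                batch = H[order[start:start + spec.batch_size]]
                if isinstance(layer, RBMLayer):
                    _, err = rbm_cd_step(layer, batch, spec.lr, rng)
                else:
                    _, err = ae_grad_step(layer, batch, spec.lr, rng)
                epoch_losses.append(err)
            loss = float(np.mean(epoch_losses))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite pretraining loss at layer {li}")
            hist.append(loss)
        histories.append(hist)
        H = stack_encode(stack, X, upto=li + 1)
    return stack, histories


def _layer_fitness_fn(layer, codes: np.ndarray, rng: np.random.Generator):
    """Negative reconstruction error of one layer as a function of its flat params.

    For RBMs the (intractable) layer log-likelihood is replaced by the
    negative mean-field one-step reconstruction error.  For denoising layers
    one corruption mask is drawn here and frozen for the whole layer
    optimization, keeping candidate fitness deterministic and comparable.
    """
    mask = None
    if getattr(layer, "corruption_rate", 0.0) > 0.0:
        mask = (rng.random(codes.shape) >= layer.corruption_rate).astype(float)

    def fitness(vec: np.ndarray) -> float:
        cand = restore_params(layer, vec)
        if isinstance(cand, RBMLayer):
            return -rbm_reconstruction_error(cand, codes)
        return -ae_reconstruction_loss(cand, codes, corruption_mask=mask)

    return fitness


def pretrain_evolutionary(stack: DeepStack, X: np.ndarray, spec: TrainSpec
                          ) -> DeepStack:
    """Layerwise WWO pretraining: each layer's full parameter set is evolved
    to maximize its negative reconstruction error before its codes feed the
    next layer."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lo, hi = spec.weight_bounds
    H = X
    for li, layer in enumerate(stack.layers):
        rng = np.random.default_rng(_sub_seed(spec.seed, 50 + li))
        fitness = _layer_fitness_fn(layer, H, rng)
        D = flatten_params(layer).size
        cfg = WWOConfig(
            bounds=np.tile([lo, hi], (D, 1)),
            population_size=spec.wwo_population,
            alpha=spec.wwo_alpha,
            lambda_init=spec.wwo_lambda_init,
            budget=spec.wwo_pretrain_budget,
            seed=_sub_seed(spec.seed, 70 + li),
        )
        result = optimize(fitness, cfg)
        trained = restore_params(layer, result.best_position)
        stack.layers[li] = trained
        H = stack_encode(stack, X, upto=li + 1)
    return stack


# ---------------------------------------------------------------------------
# stage 2: supervised fine-tuning
# ---------------------------------------------------------------------------

def _encoder_wb(layer) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(layer, RBMLayer):
        return layer.w, layer.c
    return layer.w, layer.b


def encoder_gradients(stack: DeepStack, head: GMMHead, X: np.ndarray,
                      y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradient of the mean squared error w.r.t. each layer's (W, b).

    Back-propagates through the GMM head's conditional mean (analytic
    gradient) and the sigmoid encoder chain.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    acts = [X]
    for layer in stack.layers:
        W, b = _encoder_wb(layer)
        acts.append(1.0 / (1.0 + np.exp(-np.clip(acts[-1] @ W + b, -700, 700))))
    yhat, dy_dz = gmm_predict_grad(head, acts[-1])
    upstream = (2.0 * (yhat - y) / len(y))[:, None] * dy_dz
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(stack.layers)
    for li in range(len(stack.layers) - 1, -1, -1):
        A = acts[li + 1]
        delta = upstream * A * (1.0 - A)
        gW = acts[li].T @ delta
        gb = delta.sum(axis=0)
        grads[li] = (gW, gb)
        W, _ = _encoder_wb(stack.layers[li])
        upstream = delta @ W.T
    return grads


def _fit_head(stack: DeepStack, X: np.ndarray, y: np.ndarray, spec: TrainSpec
              ) -> GMMHead:
    codes = stack_encode(stack, X)
    K = min(spec.gmm_k, len(y))
    return gmm_fit_joint(codes, y, K=K, seed=_sub_seed(spec.seed, 7))


def _training_rmse(stack: DeepStack, head: GMMHead, X: np.ndarray,
                   y: np.ndarray) -> float:
    return _rmse(gmm_predict(head, stack_encode(stack, X)), y)


def finetune_gradient(stack: DeepStack, head: GMMHead, X: np.ndarray,
                      y: np.ndarray, spec: TrainSpec
                      ) -> tuple[DeepStack, GMMHead]:
    """Gradient fine-tuning of the encoder under the squared-error objective.

    The GMM head is refit on current codes every ``head_refresh`` epochs and
    frozen in between.  Returns the training-RMSE-best snapshot, which is
    never worse than the pretrained-plus-head starting point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    from .models.stack import _clone  # snapshot helper

    best_stack, best_head = _clone(stack), head
    best_rmse = _training_rmse(stack, head, X, y)
    for epoch in range(spec.finetune_epochs):
        if spec.head_refresh > 0 and epoch > 0 and epoch % spec.head_refresh == 0:
            head = _fit_head(stack, X, y, spec)
        grads = encoder_gradients(stack, head, X, y)
        for layer, (gW, gb) in zip(stack.layers, grads):
            if not (np.all(np.isfinite(gW)) and np.all(np.isfinite(gb))):
                raise TrainingError("non-finite fine-tuning gradient")
            W, b = _encoder_wb(layer)
            W -= spec.finetune_lr * gW
            b -= spec.finetune_lr * gb
        r = _training_rmse(stack, head, X, y)
        if r < best_rmse:
            best_rmse = r
            best_stack, best_head = _clone(stack), head
    return best_stack, best_head


def finetune_evolutionary(stack: DeepStack, head: GMMHead, X: np.ndarray,
                          y: np.ndarray, spec: TrainSpec
                          ) -> tuple[DeepStack, GMMHead]:
    """WWO fine-tuning of the whole flattened encoder vector.

    Candidate fitness is 1/(training RMSE + 1e-12) scored under a head that
    is refit once per WWO generation on the current best wave's codes and
    frozen within the generation.  One initial wave is seeded from the
    pretrained parameters.  The returned model is the better (by training
    RMSE, each under a freshly refitted head) of the best wave and the
    pretrained baseline, so fine-tuning never degrades training fitness.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    lo, hi = spec.weight_bounds
    pretrained_vec = np.clip(flatten_encoder(stack), lo, hi)
    D = pretrained_vec.size

    state = {"head": head}

    def fitness(vec: np.ndarray) -> float:
        cand = restore_encoder(stack, vec)
        r = _training_rmse(cand, state["head"], X, y)
        return 1.0 / (r + 1e-12)

    def hook(best_wave, generation):
        cand = restore_encoder(stack, best_wave.position)
        state["head"] = _fit_head(cand, X, y, spec)

    cfg = WWOConfig(
        bounds=np.tile([lo, hi], (D, 1)),
        population_size=spec.wwo_population,
        alpha=spec.wwo_alpha,
        lambda_init=spec.wwo_lambda_init,
        budget=spec.wwo_finetune_budget,
        seed=_sub_seed(spec.seed, 99),
    )
    result = optimize(fitness, cfg, initial_positions=[pretrained_vec],
                      generation_hook=hook)

    best_stack = restore_encoder(stack, result.best_position)
    best_head = _fit_head(best_stack, X, y, spec)
    # never return worse than the pretrained model as handed in
    if _training_rmse(stack, head, X, y) < \
            _training_rmse(best_stack, best_head, X, y):
        return stack, head
    return best_stack, best_head


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def train_model(kind: str, X: np.ndarray, y: np.ndarray, spec: TrainSpec | None = None):
    """Train one of the eight model kinds on preprocessed (imputed,
    standardized) features; returns an object with predict(x) -> morbidity
    (clipped to [0, 1])."""
    if spec is None:
        spec = TrainSpec(model_kind=kind)
    elif spec.model_kind != kind:
        spec = replace(spec, model_kind=kind)
    if kind not in MODEL_KINDS:
        raise ValidationError(f"unknown model kind {kind!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)

    if kind == "MLR":
        return MLRPredictor(mlr_fit(X, y))
    if kind == "ANN":
        return ANNPredictor(ann_train_backprop(
            X, y, epochs=spec.epochs, lr=spec.lr, seed=spec.seed,
            batch_size=spec.batch_size))

    stack_kind = {"DBN": "DBN", "EvoDBN": "DBN", "DAE": "DAE", "EvoDAE": "DAE",
                  "DDAE": "DDAE", "EvoDDAE": "DDAE"}[kind]
    evolutionary = kind.startswith("Evo")
    rng = np.random.default_rng(_sub_seed(spec.seed, 1))
    stack = init_stack(stack_kind, X.shape[1], spec.hidden_sizes,
                       corruption_rate=spec.corruption, rng=rng)
    if evolutionary:
        stack = pretrain_evolutionary(stack, X, spec)
        head = _fit_head(stack, X, y, spec)
        stack, head = finetune_evolutionary(stack, head, X, y, spec)
    else:
        stack, _ = pretrain_gradient(stack, X, spec)
        head = _fit_head(stack, X, y, spec)
        stack, head = finetune_gradient(stack, head, X, y, spec)
    return DeepPredictor(stack, head)
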