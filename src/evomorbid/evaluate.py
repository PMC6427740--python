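"""Metrics, cross-validation, lag sweep, and the eight-model comparison.

The objective metric is RMSE (Eq.-style root mean squared error on the
morbidity scale).  The reported "prediction accuracy" percentage is the
complement of the total absolute relative error,

    acc = 100 * max(0, 1 - sum|y_i - yexp_i| / sum yexp_i),

which yields 0-100% values, is scale-invariant, and is robust to individual
zero targets.  All cross-validation computes imputation/standardization
statistics on the training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import (LaggedPairs, PredictionDataset, Preprocessor,
                   make_lagged_pairs, split_kfold)
from .errors import ValidationError
from .training import MODEL_KINDS, TrainSpec, train_model

__all__ = ["rmse", "accuracy_pct", "CVResult", "LagSweepResult",
           "EvaluationReport", "cross_validate", "lag_sweep", "compare_models",
           "DEFAULT_LAG_POLICY"]

# study lag policy: 1 week for the acute diseases, 3 weeks for chronic
# gastroenteritis and ulcers, per-model best lag for tumors
DEFAULT_LAG_POLICY: dict[str, int | str] = {
    "acute gastroenteritis": 1,
    "chronic gastroenteritis": 3,
    "gastrointestinal ulcers": 3,
    "gastrointestinal tumors": "argmin",
    "food poisoning": 1,
    "other gastrointestinal infections": 1,
}


def rmse(actual: np.ndarray, expected: np.ndarray) -> float:
    """Root mean squared error between model outputs and expected outputs."""
    a = np.asarray(actual, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape or a.size == 0:
        raise ValidationError("rmse needs equal-length non-empty vectors")
    return float(np.sqrt(np.mean((a - e) ** 2)))


def accuracy_pct(actual: np.ndarray, expected: np.ndarray) -> float:
    """Prediction accuracy in percent: 100 * max(0, 1 - sum|err| / sum expected).

    If the expected totals are zero, returns 100 for a perfect all-zero
    prediction and 0 otherwise.
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape:
        raise ValidationError("accuracy_pct needs equal-length vectors")
    denom = float(np.sum(e))
    if denom == 0.0:
        return 100.0 if np.all(a == 0.0) else 0.0
    return 100.0 * max(0.0, 1.0 - float(np.sum(np.abs(a - e))) / denom)


def default_benchmark_spec(kind: str, seed: int = 0) -> TrainSpec:
    """Desk-scale benchmark hyperparameters: a light 24-8 stack with modest
    gradient and WWO budgets, sized for the default synthetic datasets."""
    return TrainSpec(model_kind=kind, hidden_sizes=(24, 8), epochs=25,
                     finetune_epochs=30, wwo_population=8,
                     wwo_pretrain_budget=400, wwo_finetune_budget=300,
                     seed=seed)


@dataclass
class CVResult:
    """One (model kind, disease, lag) cross-validation row."""

    model_kind: str
    disease: str
    lag: int
    seed: int
    fold_rmse: list[float]
    fold_accuracy: list[float]
    fold_predictions: list | None = None

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.fold_rmse))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))


@dataclass
class LagSweepResult:
    """Mean CV RMSE per candidate lag; best_lag is the argmin (ties -> smaller)."""

    model_kind: str
    disease: str
    lags: list[int]
    mean_rmse: list[float]

    @property
    def best_lag(self) -> int:
        arr = np.asarray(self.mean_rmse)
        return int(self.lags[int(np.argmin(arr))])  # argmin takes first = smallest lag


@dataclass
class EvaluationReport:
    """Model-by-disease grid of cross-validated metrics."""

    rows: list[CVResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(dict(model_kind=r.model_kind, disease=r.disease,
                             lag=r.lag, seed=r.seed,
                             mean_rmse=r.mean_rmse, mean_accuracy=r.mean_accuracy,
                             fold_rmse=r.fold_rmse, fold_accuracy=r.fold_accuracy))
        return pd.DataFrame(recs)

    def to_json_dict(self) -> dict:
        rows = []
        for r in self.rows:
            d = asdict(r)
            d.pop("fold_predictions", None)
            rows.append(d)
        return {"accuracy_definition":
                "100 * max(0, 1 - sum|y - yexp| / sum yexp)",
                "rows": rows}


def _evaluate_folds(kind: str, pairs: LaggedPairs, k: int, seed: int,
                    spec: TrainSpec | None,
                    keep_predictions: bool = False) -> CVResult:
    if len(pairs) < k:
        raise ValidationError(f"{len(pairs)} pairs cannot fill {k} folds")
    folds = split_kfold(len(pairs), k, seed)
    all_idx = np.arange(len(pairs))
    fold_rmse, fold_acc, fold_pred = [], [], []
    for fold in folds:
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[fold] = True
        train_idx = all_idx[~test_mask]
        prep = Preprocessor().fit(pairs.X[train_idx])
        X_train = prep.transform(pairs.X[train_idx])
        X_test = prep.transform(pairs.X[fold])
        model = train_model(kind, X_train, pairs.y[train_idx], spec)
        pred = model.predict(X_test)
        fold_rmse.append(rmse(pred, pairs.y[fold]))
        fold_acc.append(accuracy_pct(pred, pairs.y[fold]))
        if keep_predictions:
            fold_pred.append((fold.copy(), np.asarray(pred).copy()))
    return CVResult(model_kind=kind, disease=pairs.disease, lag=pairs.lag,
                    seed=seed, fold_rmse=fold_rmse, fold_accuracy=fold_acc,
                    fold_predictions=fold_pred if keep_predictions else None)


def cross_validate(kind: str, ds: PredictionDataset, disease: str, lag: int,
                   k: int = 5, seed: int = 0,
                   spec: TrainSpec | None = None,
                   keep_predictions: bool = False) -> CVResult:
    """k-fold cross-validation of one model kind on one disease at one lag.

    Per fold: imputation/standardization statistics come from the k-1
    training folds only, the model is trained on them, and both metrics are
    computed on the held-out fold.  Deterministic for a fixed seed.
    """
    pairs = make_lagged_pairs(ds, disease, lag)
    return _evaluate_folds(kind, pairs, k, seed, spec,
                           keep_predictions=keep_predictions)


def lag_sweep(kind: str, ds: PredictionDataset, disease: str,
              lags=range(1, 9), k: int = 5, seed: int = 0,
              spec: TrainSpec | None = None) -> LagSweepResult:
    """Cross-validated RMSE for each candidate lag (default 1-8 weeks)."""
    lags = list(lags)
    means = []
    for lag in lags:
        cv = cross_validate(kind, ds, disease, lag, k=k, seed=seed, spec=spec)
        means.append(cv.mean_rmse)
    return LagSweepResult(model_kind=kind, disease=disease,
                          lags=lags, mean_rmse=means)


def compare_models(ds: PredictionDataset, diseases=None, spec: TrainSpec | None = None,
                   kinds=MODEL_KINDS, lag_policy: dict | None = None,
                   k: int = 5, seed: int = 0) -> EvaluationReport:
    """The full model x disease grid of cross-validated metrics.

    ``lag_policy`` maps each disease to a fixed lag (int) or "argmin", which
    runs a lag sweep per model and uses its best lag (ties to the smaller
    lag).  Diseases default to the dataset's list; unknown policy entries
    default to lag 1.
    """
    if diseases is None:
        diseases = list(ds.diseases)
    if lag_policy is None:
        lag_policy = DEFAULT_LAG_POLICY
    report = EvaluationReport()
    for disease in diseases:
        policy = lag_policy.get(disease, 1)
        for kind in kinds:
            if policy == "argmin":
                sweep = lag_sweep(kind, ds, disease, k=k, seed=seed, spec=spec)
                lag = sweep.best_lag
            else:
                lag = int(policy)
            report.rows.append(
                cross_validate(kind, ds, disease, lag, k=k, seed=seed, spec=spec))
    return report


def plot_lag_sweep(results: list[LagSweepResult], path):
    """RMSE-vs-lag curves, one line per model kind."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        ax.plot(res.lags, res.mean_rmse, marker="o", label=res.model_kind)
    ax.set_xlabel("time lag (weeks)")
    ax.set_ylabel("mean CV RMSE")
    ax.set_title(results[0].disease if results else "")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_bars(report: EvaluationReport, path):
    """Grouped accuracy bars per disease, one group per model kind."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_frame()
    diseases = df["disease"].unique()
    kinds = df["model_kind"].unique()
    fig, axes = plt.subplots(len(diseases), 1,
                             figsize=(7, 2.2 * len(diseases)), squeeze=False)
    for ax, disease in zip(axes[:, 0], diseases):
        sub = df[df["disease"] == disease].set_index("model_kind")
        vals = [sub.loc[k, "mean_accuracy"] if k in sub.index else 0.0
                for k in kinds]
        ax.bar(range(len(kinds)), vals)
        ax.set_xticks(range(len(kinds)), kinds, rotation=30, fontsize=7)
        ax.set_ylabel("accuracy (%)")
        ax.set_title(disease, fontsize=9)
        ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
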