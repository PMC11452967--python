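"""Evaluation metrics and the multi-seed ensembling protocol.

Regression is scored by the mean squared error pooled over all trait entries
and by the Pearson correlation r averaged across traits. Classification is
scored by accuracy and macro one-vs-rest AUC on a 0-100 scale and by the
multi-class Brier score in its original K-term form (range [0, 2]): the mean
over samples of the squared distance between the predicted probability
vector and the one-hot outcome.

`ensemble_evaluate` reruns a model under several seeds, averages the
predictions into an ensemble, and reports each metric's per-seed mean +/-
standard deviation alongside the ensemble-prediction metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "mse_mean",
    "pearson_r_mean",
    "accuracy",
    "auc_macro",
    "brier_multiclass",
    "ensemble_evaluate",
    "regression_metrics",
    "classification_metrics",
]


def mse_mean(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Mean squared error over all n*k residuals."""
    Y, Yhat = np.asarray(Y, float), np.asarray(Yhat, float)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    return float(np.mean((Y - Yhat) ** 2))


def pearson_r_mean(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Per-trait Pearson correlation, arithmetic mean over traits."""
    Y = np.atleast_2d(np.asarray(Y, float).T).T
    Yhat = np.atleast_2d(np.asarray(Yhat, float).T).T
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch {Y.shape} vs {Yhat.shape}")
    rs = []
    for t in range(Y.shape[1]):
        y, yh = Y[:, t], Yhat[:, t]
        if y.std() == 0 or yh.std() == 0:
            raise ValueError(f"correlation undefined for constant trait column {t}")
        rs.append(np.corrcoef(y, yh)[0, 1])
    return float(np.mean(rs))


def accuracy(labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Percentage of correct class predictions (0-100 scale)."""
    labels = np.asarray(labels).ravel()
    predicted_labels = np.asarray(predicted_labels).ravel()
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.size != predicted_labels.size:
        raise ValueError("length mismatch")
    return float(100.0 * np.mean(labels == predicted_labels))


def _check_probs(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, float)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("class probability rows must sum to 1")
    return P


def auc_macro(labels: np.ndarray, class_probabilities: np.ndarray) -> float:
    """One-vs-rest AUC per class present in `labels`, macro-averaged, x100."""
    labels = np.asarray(labels).ravel()
    P = _check_probs(class_probabilities)
    present = np.unique(labels)
    if P.shape[1] > present.size:
        absent = sorted(set(range(P.shape[1])) - set(present.tolist()))
        warnings.warn(f"classes absent from labels excluded from AUC: {absent}",
                      stacklevel=2)
    aucs = []
    for c in present:
        y = (labels == c).astype(int)
        if y.all():  # single-class labels: AUC undefined
            continue
        aucs.append(roc_auc_score(y, P[:, int(c)]))
    if not aucs:
        raise ValueError("AUC undefined: fewer than two classes present")
    return float(100.0 * np.mean(aucs))


def brier_multiclass(labels: np.ndarray, class_probabilities: np.ndarray) -> float:
    """Original multi-class Brier score: mean_i sum_k (p_ik - o_ik)^2, in [0, 2]."""
    labels = np.asarray(labels).ravel()
    P = _check_probs(class_probabilities)
    onehot = np.zeros_like(P)
    onehot[np.arange(labels.size), labels.astype(int)] = 1.0
    return float(np.mean(np.sum((P - onehot) ** 2, axis=1)))


def regression_metrics(Y, Yhat) -> dict:
    return {"mse": mse_mean(Y, Yhat), "r": pearson_r_mean(Y, Yhat)}


def classification_metrics(labels, probs) -> dict:
    pred = np.argmax(np.asarray(probs), axis=1)
    return {
        "accuracy": accuracy(labels, pred),
        "auc": auc_macro(labels, probs),
        "brier": brier_multiclass(labels, probs),
    }


@dataclass
class MetricsReport:
    """Per-seed mean/stddev and ensemble-prediction value for each metric."""

    task: str
    n_seeds: int
    seeds: list
    per_seed: dict  # metric -> list of per-seed values
    mean: dict  # metric -> mean over seeds
    stddev: dict  # metric -> stddev over seeds (ddof=0)
    ensemble: dict  # metric -> metric of the averaged prediction
    per_trait: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "n_seeds": self.n_seeds,
            "seeds": list(map(int, self.seeds)),
            "per_seed": {m: list(map(float, v)) for m, v in self.per_seed.items()},
            "mean": self.mean,
            "stddev": self.stddev,
            "ensemble": self.ensemble,
            "per_trait": self.per_trait,
        }


def ensemble_evaluate(run_fn, Y_test, task: str = "regression",
                      n_seeds: int = 10, seeds=None) -> MetricsReport:
    """Run `run_fn(seed)` for each seed, average predictions, report metrics.

    For regression `run_fn` returns an n x k prediction matrix; for
    classification an n x K class-probability matrix. Any run failure aborts
    with the failing seed in the error message.
    """
    if seeds is None:
        seeds = list(range(n_seeds))
    seeds = list(seeds)
    preds = []
    for s in seeds:
        try:
            preds.append(np.asarray(run_fn(s), dtype=float))
        except Exception as exc:  # noqa: BLE001 - reraise with seed context
            raise RuntimeError(f"ensemble run failed for seed {s}: {exc}") from exc

    score = regression_metrics if task == "regression" else classification_metrics
    Y_test = np.asarray(Y_test)
    per_seed = {}
    for pred in preds:
        for m, v in score(Y_test, pred).items():
            per_seed.setdefault(m, []).append(v)
    ens_pred = np.mean(preds, axis=0)
    if task == "classification":
        ens_pred = ens_pred / ens_pred.sum(axis=1, keepdims=True)
    ensemble = score(Y_test, ens_pred)

    per_trait = {}
    if task == "regression" and Y_test.ndim == 2:
        for t in range(Y_test.shape[1]):
            per_trait[f"trait_{t}"] = {
                "mse": mse_mean(Y_test[:, t], ens_pred[:, t]),
                "r": pearson_r_mean(Y_test[:, t], ens_pred[:, t]),
            }

    return MetricsReport(
        task=task,
        n_seeds=len(seeds),
        seeds=seeds,
        per_seed=per_seed,
        mean={m: float(np.mean(v)) for m, v in per_seed.items()},
        stddev={m: float(np.std(v)) for m, v in per_seed.items()},
        ensemble=ensemble,
        per_trait=per_trait,
    )
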