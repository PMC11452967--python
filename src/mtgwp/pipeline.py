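"""Benchmark orchestration: baselines, end-to-end runs, reports.

Implements the evaluation pipeline used throughout the package: simulate (or
load) a genotype/phenotype dataset, split 70/10/20, optionally tune each
model by cross-validated Bayesian optimization, train with each of the
requested seeds, ensemble the predictions, and collect per-model metric
reports plus selected-feature counts where the model supports selection.

Baselines: gradient-boosted decision trees (LightGBM, one booster per trait
for regression / multiclass objective for classification) and a plain
multi-task feed-forward network. The MLP baseline is LassoNet trained with
lambda = 0 and no hierarchy constraint — the nu -> infinity limit of the
same architecture — so the two are identical by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import gandalf as gd
from . import lassonet as ln
from .metrics import MetricsReport, ensemble_evaluate
from .simdata import DataSplit, SimConfig, simulate_genotypes, simulate_traits, split_data

__all__ = [
    "RunConfig",
    "BenchmarkReport",
    "fit_gbdt_baseline",
    "fit_mlp_baseline",
    "run_benchmark",
    "standardize_genotypes",
]


def standardize_genotypes(values: np.ndarray) -> np.ndarray:
    """Column-standardize an integer genotype matrix for network input."""
    X = np.asarray(values, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    models: tuple = ("lassonet", "gandalf", "gbdt", "mlp")
    task: str = "regression"
    seeds: tuple = tuple(range(10))
    fractions: tuple = (0.7, 0.1, 0.2)
    lassonet: ln.LassoNetConfig = field(default_factory=ln.LassoNetConfig)
    gandalf: gd.GandalfConfig = field(default_factory=gd.GandalfConfig)
    gbdt_params: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self):
        if not self.models:
            raise ValueError("models list must be non-empty")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique")

    def hash(self) -> str:
        doc = {
            "sim": vars(self.sim),
            "models": list(self.models),
            "task": self.task,
            "seeds": list(self.seeds),
            "fractions": list(self.fractions),
            "lassonet": {k: (None if v is None else (str(v) if isinstance(v, str) else v))
                         for k, v in vars(self.lassonet).items()},
            "gandalf": vars(self.gandalf),
            "gbdt": self.gbdt_params,
        }
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BenchmarkReport:
    per_model: dict  # model name -> MetricsReport (or error string)
    selected_counts: dict  # model name -> per-trait selection counts
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "per_model": {
                m: (r.to_dict() if isinstance(r, MetricsReport) else {"error": r})
                for m, r in self.per_model.items()
            },
            "selected_counts": self.selected_counts,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

_LGB_DETERMINISM = dict(deterministic=True, force_row_wise=True, n_jobs=1,
                        verbosity=-1)


def fit_gbdt_baseline(X, Y, split: DataSplit, params: dict | None = None,
                      task: str = "regression", seed: int = 0):
    """LightGBM baseline: one booster per trait, or multiclass objective.

    Returns test-partition predictions (n_test x k traits, or n_test x K
    class probabilities). Fully deterministic for a fixed seed.
    """
    import lightgbm as lgb

    params = dict(params or {})
    params.setdefault("n_estimators", 200)
    params.setdefault("learning_rate", 0.05)
    params.setdefault("num_leaves", 31)
    X = np.asarray(X, dtype=float)
    Xtr, Xte = X[split.train_idx], X[split.test_idx]
    if task == "regression":
        Y = np.asarray(Y, dtype=float)
        preds = np.empty((len(split.test_idx), Y.shape[1]))
        for t in range(Y.shape[1]):
            model = lgb.LGBMRegressor(random_state=seed, **_LGB_DETERMINISM, **params)
            model.fit(Xtr, Y[split.train_idx, t])
            preds[:, t] = model.predict(Xte)
        return preds
    labels = np.asarray(Y, dtype=int)
    model = lgb.LGBMClassifier(objective="multiclass", random_state=seed,
                               **_LGB_DETERMINISM, **params)
    model.fit(Xtr, labels[split.train_idx])
    return model.predict_proba(Xte)


def fit_mlp_baseline(X, Y, split: DataSplit, config: ln.LassoNetConfig | None = None):
    """Plain multi-task feed-forward baseline (shared hidden layers, k-head).

    Trained through the same routine as the LassoNet dense warm start with
    lambda = 0 and nu = inf, which is exactly the unconstrained network limit.
    Returns test-partition predictions.
    """
    if config is None:
        config = ln.LassoNetConfig()
    cfg = ln.LassoNetConfig(**{**vars(config), "nu": np.inf})
    model = ln.train_dense(np.asarray(X, float), np.asarray(Y), split, cfg)
    return ln.predict(model, np.asarray(X, float)[split.test_idx])


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


def _lassonet_runner(X, Y, split, base_cfg: ln.LassoNetConfig, task: str):
    def run(seed: int):
        cfg = ln.LassoNetConfig(**{**vars(base_cfg), "seed": seed, "task": task})
        path = ln.fit_path(X, Y, split, cfg)
        best = ln.select_model(path)
        return ln.predict(best.model, X[split.test_idx]), best

    return run


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Simulate data, train every requested model under every seed, report.

    Per-model failures are recorded in the report and the run continues.
    The report's provenance (config hash + seeds) suffices to re-run.
    """
    G = simulate_genotypes(config.sim)
    traits, truth = simulate_traits(G, config.sim)
    X = standardize_genotypes(G.values)
    n = X.shape[0]
    split = split_data(n, config.fractions, seed=config.sim.seed)

    if config.task == "classification":
        if config.sim.n_traits != 2:
            raise ValueError("classification benchmark thresholds two traits")
        from .simdata import liability_to_fourclass

        labels = liability_to_fourclass(traits.values).values
        Y = labels
        Y_test = labels[split.test_idx]
    else:
        Y = traits.values
        Y_test = Y[split.test_idx]

    per_model, selected = {}, {}
    for name in config.models:
        try:
            if name == "lassonet":
                runner = _lassonet_runner(X, Y, split, config.lassonet, config.task)
                best_points = {}

                def run_fn(seed, _runner=runner, _bp=best_points):
                    pred, best = _runner(seed)
                    _bp[seed] = best
                    return pred

                report = ensemble_evaluate(run_fn, Y_test, task=config.task,
                                           seeds=config.seeds)
                any_best = best_points[config.seeds[0]]
                rep = ln.selected_features(any_best.model, G.marker_ids,
                                           trait_names=traits.trait_names
                                           if config.task == "regression" else None)
                selected[name] = rep.counts
            elif name == "gandalf":
                def run_fn(seed):
                    cfg = gd.GandalfConfig(**{**vars(config.gandalf),
                                              "seed": seed, "task": config.task})
                    model = gd.fit_gandalf(X, Y, split, cfg)
                    return gd.predict_gandalf(model, X[split.test_idx])

                report = ensemble_evaluate(run_fn, Y_test, task=config.task,
                                           seeds=config.seeds)
            elif name == "gbdt":
                def run_fn(seed):
                    return fit_gbdt_baseline(X, Y, split, config.gbdt_params,
                                             task=config.task, seed=seed)

                report = ensemble_evaluate(run_fn, Y_test, task=config.task,
                                           seeds=config.seeds)
            elif name == "mlp":
                def run_fn(seed):
                    cfg = ln.LassoNetConfig(**{**vars(config.lassonet),
                                               "seed": seed, "task": config.task})
                    return fit_mlp_baseline(X, Y, split, cfg)

                report = ensemble_evaluate(run_fn, Y_test, task=config.task,
                                           seeds=config.seeds)
            else:
                raise ValueError(f"unknown model {name!r}")
            per_model[name] = report
        except Exception as exc:  # noqa: BLE001 - per-model failure recorded
            per_model[name] = f"{type(exc).__name__}: {exc}"

    report = BenchmarkReport(
        per_model=per_model,
        selected_counts=selected,
        provenance={
            "config_hash": config.hash(),
            "seeds": list(config.seeds),
            "n_samples": n,
            "n_markers": X.shape[1],
            "task": config.task,
            "n_causal_truth": int(truth.all_causal.size),
        },
    )
    if config.out_dir:
        from pathlib import Path

        from .io import write_report

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report.to_dict(), out / "benchmark.json")
    return report
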