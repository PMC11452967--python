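"""Default hyperparameter search spaces and CV objectives per model.

Spaces can also be loaded from a YAML file with the same schema, e.g.::

    lassonet:
      nu: {kind: continuous, low: 0.1, high: 10, log: true}
      path_learning_rate: {kind: continuous, low: 1e-4, high: 1e-1, log: true}
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import gandalf as gd
from . import lassonet as ln
from .pipeline import fit_gbdt_baseline
from .simdata import DataSplit
from .tuning import Param, SearchSpace, cv_score

__all__ = ["default_space", "load_spaces", "make_objective"]

_DEFAULTS = {
    "lassonet": {
        "nu": Param("continuous", 0.1, 10.0, log=True),
        "path_learning_rate": Param("continuous", 1e-4, 1e-1, log=True),
        "hidden": Param("integer", 16, 128),
    },
    "gandalf": {
        "n_stages": Param("integer", 1, 6),
        "dim": Param("integer", 16, 128),
        "learning_rate": Param("continuous", 1e-4, 1e-2, log=True),
    },
    "gbdt": {
        "num_leaves": Param("integer", 7, 63),
        "learning_rate": Param("continuous", 1e-2, 0.3, log=True),
        "n_estimators": Param("integer", 50, 400),
    },
    "mlp": {
        "learning_rate": Param("continuous", 1e-4, 1e-2, log=True),
        "hidden": Param("integer", 16, 128),
    },
}


def default_space(model: str) -> SearchSpace:
    if model not in _DEFAULTS:
        raise ValueError(f"no default search space for model {model!r}")
    return SearchSpace(params=dict(_DEFAULTS[model]))


def load_spaces(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for model, params in doc.items():
        out[model] = SearchSpace(
            params={name: Param(**spec) for name, spec in params.items()}
        )
    return out


def make_objective(model: str, X, traits, split: DataSplit, k_folds: int = 5,
                   seed: int = 0):
    """Objective mapping hyperparameters to a CV score on the training split.

    Only the training partition is ever passed to the fold trainer; the test
    indices never reach the objective.
    """
    X = np.asarray(X, float)
    task = traits.mode
    Y = traits.values

    def trainer_factory(params):
        if model == "gbdt":
            def trainer(Xtr, Ytr, Xva, Yva):
                n_tr = len(Xtr)
                Xall = np.vstack([Xtr, Xva])
                Yall = np.concatenate([Ytr, Yva], axis=0)
                sp = DataSplit(
                    train_idx=np.arange(n_tr),
                    val_idx=np.array([], dtype=int),  # unused by GBDT
                    test_idx=np.arange(n_tr, len(Xall)),
                )
                pred = fit_gbdt_baseline(Xall, Yall, sp, params, task=task, seed=seed)
                return _score(Yva, pred, task)
        elif model in ("lassonet", "mlp"):
            def trainer(Xtr, Ytr, Xva, Yva):
                kw = {k: v for k, v in params.items() if k != "hidden"}
                if "hidden" in params:
                    kw["hidden_sizes"] = (int(params["hidden"]),)
                cfg = ln.LassoNetConfig(task=task, seed=seed, **kw)
                n_tr = len(Xtr)
                Xall = np.vstack([Xtr, Xva])
                Yall = np.concatenate([Ytr, Yva], axis=0)
                sp = DataSplit(train_idx=np.arange(n_tr),
                               val_idx=np.arange(n_tr, len(Xall)),
                               test_idx=np.array([], dtype=int))
                if model == "lassonet":
                    path = ln.fit_path(Xall, Yall, sp, cfg)
                    return ln.select_model(path).val_metric
                mdl = ln.train_dense(Xall, Yall, sp, cfg)
                return _score(Yva, ln.predict(mdl, Xva), task)
        elif model == "gandalf":
            def trainer(Xtr, Ytr, Xva, Yva):
                cfg = gd.GandalfConfig(task=task, seed=seed,
                                       **{k: int(v) if k in ("n_stages", "dim") else v
                                          for k, v in params.items()})
                n_tr = len(Xtr)
                Xall = np.vstack([Xtr, Xva])
                Yall = np.concatenate([Ytr, Yva], axis=0)
                sp = DataSplit(train_idx=np.arange(n_tr),
                               val_idx=np.arange(n_tr, len(Xall)),
                               test_idx=np.array([], dtype=int))
                mdl = gd.fit_gandalf(Xall, Yall, sp, cfg)
                return _score(Yva, gd.predict_gandalf(mdl, Xva), task)
        else:
            raise ValueError(f"unknown model {model!r}")
        return trainer

    def objective(params):
        trainer = trainer_factory(params)
        return cv_score(trainer, X, Y, split.train_idx, k_folds=k_folds,
                        seed=seed, task=task)

    return objective


def _score(Y, pred, task: str) -> float:
    if task == "regression":
        return float(np.mean((np.asarray(Y, float) - pred) ** 2))
    labels = np.argmax(pred, axis=1)
    return float(1.0 - np.mean(labels == np.asarray(Y, int)))
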