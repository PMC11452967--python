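"""Cross-validation scoring and Bayesian hyperparameter search."""

import numpy as np
import pytest

from mtgwp.tuning import Param, SearchSpace, cv_score, tune


def _quadratic_space():
    return SearchSpace(params={"x": Param("continuous", -2.0, 2.0)})


def test_cv_folds_are_disjoint_and_cover_training_set():
    seen = []

    def trainer(Xtr, Ytr, Xva, Yva):
        seen.append((Xtr[:, 0].astype(int), Xva[:, 0].astype(int)))
        return 0.0

    n = 53
    X = np.arange(n, dtype=float)[:, None]
    Y = np.zeros((n, 1))
    train_idx = np.arange(n)
    cv_score(trainer, X, Y, train_idx, k_folds=5, seed=0)
    all_val = np.concatenate([va for _, va in seen])
    assert len(seen) == 5
    assert sorted(all_val.tolist()) == list(range(n))  # disjoint and covering
    for tr, va in seen:
        assert set(tr) & set(va) == set()
        assert sorted(set(tr) | set(va)) == list(range(n))


def test_cv_uses_only_training_partition():
    touched = set()

    def trainer(Xtr, Ytr, Xva, Yva):
        touched.update(Xtr[:, 0].astype(int).tolist())
        touched.update(Xva[:, 0].astype(int).tolist())
        return 0.0

    X = np.arange(40, dtype=float)[:, None]
    Y = np.zeros((40, 1))
    cv_score(trainer, X, Y, np.arange(25), k_folds=5, seed=1)
    assert touched == set(range(25))


def test_cv_stratified_folds_raise_when_class_too_rare():
    X = np.zeros((20, 1))
    Y = np.array([0] * 17 + [1] * 3)
    with pytest.raises(ValueError, match="strat"):
        cv_score(lambda *a: 0.0, X, Y, np.arange(20), k_folds=5,
                 task="classification")


def test_cv_score_returns_mean_of_fold_scores():
    scores = iter([1.0, 2.0, 3.0, 4.0, 5.0])

    def trainer(Xtr, Ytr, Xva, Yva):
        return next(scores)

    mean, folds = cv_score(trainer, np.zeros((30, 1)), np.zeros((30, 1)),
                           np.arange(30), k_folds=5, seed=0)
    assert folds == [1.0, 2.0, 3.0, 4.0, 5.0]
    assert mean == 3.0


@pytest.mark.parametrize("engine", ["tpe", "random"])
def test_bo_finds_quadratic_optimum(engine):
    result = tune(_quadratic_space(), lambda p: (p["x"] - 0.7) ** 2,
                  n_iter=100, tol=None, engine=engine, seed=0)
    assert abs(result.best_parameters["x"] - 0.7) < 0.05
    assert result.stopped_reason == "budget"


def test_tolerance_stop_triggers_on_constant_objective():
    result = tune(_quadratic_space(), lambda p: 1.0, n_iter=100, tol=1e-5,
                  engine="tpe", seed=0, window=10)
    assert result.stopped_reason == "tolerance"
    assert len(result.trials) <= 12


def test_tpe_concentrates_samples_near_the_optimum():
    result = tune(_quadratic_space(), lambda p: (p["x"] - 0.7) ** 2,
                  n_iter=60, tol=None, engine="tpe", seed=1)
    late = [t.parameters["x"] for t in result.trials[30:]]
    early = [t.parameters["x"] for t in result.trials[:8]]  # random startup
    assert np.mean(np.abs(np.array(late) - 0.7)) < np.mean(np.abs(np.array(early) - 0.7))


def test_failed_trials_recorded_and_search_continues():
    calls = {"n": 0}

    def objective(p):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            raise RuntimeError("unstable configuration")
        return (p["x"]) ** 2

    result = tune(_quadratic_space(), objective, n_iter=30, tol=None, seed=2)
    assert any(t.failed for t in result.trials)
    assert np.isfinite(result.best_score)


def test_all_failures_raise():
    def objective(p):
        raise RuntimeError("always fails")

    with pytest.raises(RuntimeError, match="all tuning trials failed"):
        tune(_quadratic_space(), objective, n_iter=5, tol=None, seed=0)


def test_search_is_deterministic_given_seed():
    obj = lambda p: np.sin(3 * p["x"]) + p["x"] ** 2
    r1 = tune(_quadratic_space(), obj, n_iter=40, tol=None, seed=7)
    r2 = tune(_quadratic_space(), obj, n_iter=40, tol=None, seed=7)
    assert [t.parameters for t in r1.trials] == [t.parameters for t in r2.trials]
    assert r1.best_score == r2.best_score


def test_integer_and_categorical_sampling_respect_domains():
    space = SearchSpace(params={
        "depth": Param("integer", 2, 6),
        "kind": Param("categorical", choices=["a", "b"]),
    })
    obj = lambda p: float(p["depth"]) + (0.0 if p["kind"] == "a" else 1.0)
    result = tune(space, obj, n_iter=40, tol=None, seed=3)
    for t in result.trials:
        assert 2 <= t.parameters["depth"] <= 6
        assert t.parameters["kind"] in ("a", "b")
    assert result.best_parameters["depth"] == 2
    assert result.best_parameters["kind"] == "a"


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        Param("continuous", 1.0, 0.0)
    with pytest.raises(ValueError):
        Param("continuous", -1.0, 1.0, log=True)
    with pytest.raises(ValueError):
        Param("categorical", choices=[])
    with pytest.raises(ValueError):
        tune(_quadratic_space(), lambda p: 0.0, engine="grid")
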