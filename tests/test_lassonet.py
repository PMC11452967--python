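"""Multi-task LassoNet: training, regularization path, selection."""

import numpy as np
import pytest

from mtgwp import lassonet as ln
from mtgwp.simdata import split_data

from conftest import make_linear_dataset
from prox_oracle import feasible


def _fast_cfg(**kw):
    base = dict(hidden_sizes=(8,), epochs_dense=150, learning_rate=1e-2,
                path_multiplier=1.4, epochs_per_step=30, path_learning_rate=1e-2,
                batch_size=256, seed=0)
    base.update(kw)
    return ln.LassoNetConfig(**base)


def test_forward_is_skip_plus_network(rng):
    p, k, h = 6, 2, 4
    params = ln.init_params(p, k, (h,), seed=0)
    params["theta"] = rng.normal(size=(p, k))
    model = ln.LassoNetModel(
        theta=params["theta"], first_layer=params["W0"], first_bias=params["b0"],
        deeper_layers=[(params["W1"], params["b1"])], nu=1.0, lambda_=0.0,
    )
    X = rng.normal(size=(9, p))
    skip = X @ params["theta"]
    net = np.maximum(X @ params["W0"] + params["b0"], 0) @ params["W1"] + params["b1"]
    assert np.allclose(ln.forward(model, X), skip + net)


def test_dense_training_fits_realizable_linear_target():
    X, Y, _ = make_linear_dataset(300, 30, 2, 5, seed=1)
    split = split_data(300, seed=1)
    model = ln.train_dense(X, Y, split, _fast_cfg(epochs_dense=800, patience=50))
    pred = ln.predict(model, X[split.val_idx])
    resid = Y[split.val_idx] - pred
    assert np.mean(resid**2) < 0.1 * np.var(Y[split.val_idx])


def test_training_is_deterministic_given_seed():
    X, Y, _ = make_linear_dataset(120, 25, 2, 5, seed=2)
    split = split_data(120, seed=2)
    m1 = ln.train_dense(X, Y, split, _fast_cfg(epochs_dense=30))
    m2 = ln.train_dense(X, Y, split, _fast_cfg(epochs_dense=30))
    assert np.array_equal(m1.theta, m2.theta)
    assert np.array_equal(m1.first_layer, m2.first_layer)


def test_path_support_monotone_and_terminates_empty():
    X, Y, _ = make_linear_dataset(200, 50, 2, 6, seed=3)
    split = split_data(200, seed=3)
    path = ln.fit_path(X, Y, split, _fast_cfg())
    sizes = path.support_sizes()
    assert np.all(np.diff(sizes) <= 0)
    assert sizes[-1] == 0
    lams = path.lambdas()
    assert np.all(np.diff(lams) > 0)


def test_hierarchy_constraint_feasible_at_every_path_point():
    X, Y, _ = make_linear_dataset(150, 40, 2, 5, seed=4)
    split = split_data(150, seed=4)
    cfg = _fast_cfg(nu=0.7)
    path = ln.fit_path(X, Y, split, cfg)
    for pt in path.points:
        for i in range(pt.model.theta.shape[0]):
            assert feasible(pt.model.theta[i], pt.model.first_layer[i],
                            cfg.nu, "elementwise")


def test_path_recovers_planted_support_on_easy_problem():
    X, Y, causal = make_linear_dataset(250, 60, 2, 5, seed=5)
    split = split_data(250, seed=5)
    path = ln.fit_path(X, Y, split, _fast_cfg())
    best = ln.select_model(path)
    sup = set(best.model.support().tolist())
    assert len(set(causal.tolist()) & sup) >= 4


def test_select_model_prefers_lower_metric_then_smaller_support():
    m = ln.LassoNetModel(np.zeros((2, 1)), np.zeros((2, 2)), np.zeros(2),
                         [(np.zeros((2, 1)), np.zeros(1))], 1.0, 0.0)
    pts = [
        ln.PathPoint(0.1, m, 0.5, 10),
        ln.PathPoint(0.2, m, 0.3, 8),
        ln.PathPoint(0.3, m, 0.3, 4),
        ln.PathPoint(0.4, m, 0.6, 2),
    ]
    best = ln.select_model(ln.PathResult(points=pts, best_index=-1))
    assert best.support_size == 4


def test_classification_predicts_probability_simplex(rng):
    n, p = 160, 20
    X = rng.normal(size=(n, p))
    labels = (X[:, 0] + X[:, 1] > 0).astype(int) + 2 * (X[:, 2] > 0).astype(int)
    split = split_data(n, seed=6)
    cfg = _fast_cfg(task="classification", epochs_dense=60)
    model = ln.train_dense(X, labels, split, cfg)
    P = ln.predict(model, X[split.test_idx])
    assert P.shape == (len(split.test_idx), 4)
    assert np.allclose(P.sum(axis=1), 1.0)
    assert np.all(P >= 0)


def test_selected_features_report_counts_match():
    theta = np.array([[0.5, 0.0], [0.0, 0.0], [-0.2, 0.1]])
    model = ln.LassoNetModel(theta, np.zeros((3, 2)), np.zeros(2),
                             [(np.zeros((2, 2)), np.zeros(2))], 1.0, 0.0)
    rep = ln.selected_features(model, marker_ids=["a", "b", "c"],
                               trait_names=["t1", "t2"])
    assert rep.counts == {"t1": 2, "t2": 1}
    assert [m for m, _ in rep.per_trait["t1"]] == ["a", "c"]


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ln.LassoNetConfig(path_multiplier=1.0)
    with pytest.raises(ValueError):
        ln.LassoNetConfig(nu=-1.0)
    with pytest.raises(ValueError):
        ln.LassoNetConfig(task="ranking")


def test_divergence_reported_with_actionable_message():
    X, Y, _ = make_linear_dataset(80, 10, 1, 3, seed=7)
    split = split_data(80, seed=7)
    cfg = _fast_cfg(dense_optimizer="sgd", learning_rate=1e6, epochs_dense=50)
    with np.errstate(all="ignore"), pytest.raises(ln.DivergenceError,
                                                  match="learning rate"):
        ln.train_dense(X, Y, split, cfg)


def test_auto_lambda_start_positive_and_path_starts_dense():
    X, Y, _ = make_linear_dataset(150, 40, 2, 5, seed=8)
    split = split_data(150, seed=8)
    path = ln.fit_path(X, Y, split, _fast_cfg())
    # the first path point should not already be fully sparse
    assert path.points[0].support_size > 0
    assert path.points[0].lambda_ > 0
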