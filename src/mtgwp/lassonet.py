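"""Multi-task LassoNet: residual network with an L1-penalized skip connection.

The model is f(X) = X @ theta + g_W(X): a linear skip connection (theta is
p x k, one coefficient per marker and trait) plus a feed-forward network whose
hidden layers are shared across tasks and whose output layer maps the shared
representation to k outputs jointly. Sparsity comes from the hierarchy
constraint ||W_i^(1)||_inf <= nu * sel(theta_i): a marker may feed the
nonlinear pathway only while its skip coefficient is active, so zeroing a
theta row removes the feature from the whole network.

Training follows the dense-to-sparse protocol: an unpenalized dense warm
start (Adam by default), then a regularization path over geometrically
increasing lambda where every gradient step (SGD with momentum) is followed
by the exact hierarchical proximal operator on all feature rows. nu = 0
collapses the model to the multi-task Lasso; nu = inf with lambda = 0 is a
plain unregularized residual feed-forward network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, SGD, Tensor, cross_entropy, mse_loss
from .prox import hier_prox_batch
from .simdata import DataSplit

__all__ = [
    "LassoNetConfig",
    "LassoNetModel",
    "PathPoint",
    "PathResult",
    "SelectionReport",
    "DivergenceError",
    "forward",
    "predict",
    "train_dense",
    "fit_path",
    "select_model",
    "selected_features",
    "init_params",
]


class DivergenceError(RuntimeError):
    pass


@dataclass
class LassoNetConfig:
    hidden_sizes: tuple | None = None  # default: (min(100, max(p // 3, 8)),)
    nu: float = 1.0  # hierarchy coefficient (a.k.a. M); 0 = Lasso, inf = MLP
    path_multiplier: float = 1.02
    lambda_start: float | str = "auto"
    epochs_dense: int = 200
    epochs_per_step: int = 10
    learning_rate: float = 1e-3  # dense warm start (Adam)
    path_learning_rate: float = 5e-3  # path steps (SGD + momentum)
    momentum: float = 0.9
    batch_size: int = 64
    patience: int = 20
    seed: int = 0
    task: str = "regression"
    convention: str = "elementwise"  # or "group"
    dense_optimizer: str = "adam"  # or "sgd"
    tol: float | None = None  # optional inner convergence stop per lambda step
    max_path_steps: int = 1000

    def __post_init__(self):
        if self.path_multiplier <= 1.0:
            raise ValueError("path_multiplier must be > 1")
        for name in ("epochs_dense", "epochs_per_step", "batch_size", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.nu < 0:
            raise ValueError("nu must be >= 0 (np.inf allowed)")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class LassoNetModel:
    theta: np.ndarray  # p x k skip coefficients
    first_layer: np.ndarray  # p x h1
    first_bias: np.ndarray  # h1
    deeper_layers: list  # [(W, b), ...] ending with the k-output head
    nu: float
    lambda_: float
    task: str = "regression"

    @property
    def n_features(self) -> int:
        return self.theta.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.theta.shape[1]

    def support(self) -> np.ndarray:
        """Indices of features with a nonzero theta row."""
        return np.flatnonzero(np.abs(self.theta).max(axis=1) > 0)

    def copy(self) -> "LassoNetModel":
        return LassoNetModel(
            theta=self.theta.copy(),
            first_layer=self.first_layer.copy(),
            first_bias=self.first_bias.copy(),
            deeper_layers=[(W.copy(), b.copy()) for W, b in self.deeper_layers],
            nu=self.nu,
            lambda_=self.lambda_,
            task=self.task,
        )


@dataclass
class PathPoint:
    lambda_: float
    model: LassoNetModel
    val_metric: float  # lower is better (MSE, or 1 - accuracy/100)
    support_size: int


@dataclass
class PathResult:
    points: list
    best_index: int

    def lambdas(self) -> np.ndarray:
        return np.array([pt.lambda_ for pt in self.points])

    def support_sizes(self) -> np.ndarray:
        return np.array([pt.support_size for pt in self.points])


@dataclass
class SelectionReport:
    per_trait: dict  # trait name -> list of (marker_id, coefficient)
    counts: dict = field(default_factory=dict)  # trait name -> count

    def __post_init__(self):
        if not self.counts:
            self.counts = {t: len(v) for t, v in self.per_trait.items()}
        for t, v in self.per_trait.items():
            if self.counts[t] != len(v):
                raise ValueError("selection counts inconsistent with lists")


# ---------------------------------------------------------------------------
# parameter handling and forward pass
# ---------------------------------------------------------------------------


def _default_hidden(p: int) -> tuple:
    return (min(100, max(p // 3, 8)),)


def init_params(p: int, k: int, hidden_sizes: tuple, seed: int) -> dict:
    """He-style initialization; theta starts at zero (selection is learned)."""
    rng = np.random.default_rng(seed)
    params = {"theta": np.zeros((p, k))}
    dims = [p, *hidden_sizes, k]
    for li in range(len(dims) - 1):
        fan_in = dims[li]
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(dims[li], dims[li + 1]))
        b = np.zeros(dims[li + 1])
        params[f"W{li}"] = W
        params[f"b{li}"] = b
    return params


def _to_tensors(params: dict) -> dict:
    return {k: Tensor(v.copy(), requires_grad=True) for k, v in params.items()}


def _n_layers(params: dict) -> int:
    return sum(1 for k in params if k.startswith("W"))


def _forward_t(params: dict, X: Tensor) -> Tensor:
    nl = _n_layers(params)
    z = X
    for li in range(nl):
        z = z @ params[f"W{li}"] + params[f"b{li}"]
        if li < nl - 1:
            z = z.relu()
    return X @ params["theta"] + z


def _loss_t(params: dict, X: np.ndarray, Y: np.ndarray, task: str) -> Tensor:
    out = _forward_t(params, Tensor(X))
    if task == "regression":
        return mse_loss(out, Y)
    return cross_entropy(out, Y)


def _params_to_model(params: dict, nu: float, lambda_: float, task: str) -> LassoNetModel:
    nl = _n_layers(params)
    get = lambda k: params[k].data if isinstance(params[k], Tensor) else params[k]
    deeper = [(get(f"W{li}").copy(), get(f"b{li}").copy()) for li in range(1, nl)]
    return LassoNetModel(
        theta=get("theta").copy(),
        first_layer=get("W0").copy(),
        first_bias=get("b0").copy(),
        deeper_layers=deeper,
        nu=nu,
        lambda_=lambda_,
        task=task,
    )


def _model_to_params(model: LassoNetModel) -> dict:
    params = {"theta": model.theta.copy(), "W0": model.first_layer.copy(),
              "b0": model.first_bias.copy()}
    for i, (W, b) in enumerate(model.deeper_layers, start=1):
        params[f"W{i}"] = W.copy()
        params[f"b{i}"] = b.copy()
    return params


def forward(model: LassoNetModel, X: np.ndarray) -> np.ndarray:
    """Skip-connection term plus network term; logits for classification."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} columns, model expects {model.n_features}"
        )
    z = np.maximum(X @ model.first_layer + model.first_bias, 0.0)
    for W, b in model.deeper_layers[:-1]:
        z = np.maximum(z @ W + b, 0.0)
    W, b = model.deeper_layers[-1]
    return X @ model.theta + z @ W + b


def predict(model: LassoNetModel, X: np.ndarray) -> np.ndarray:
    """Predicted traits (regression) or class probabilities (classification)."""
    out = forward(model, X)
    if model.task == "regression":
        return out
    z = out - out.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _val_loss(params: dict, X: np.ndarray, Y: np.ndarray, task: str) -> float:
    arrs = {k: (v.data if isinstance(v, Tensor) else v) for k, v in params.items()}
    model = _params_to_model(arrs, 0.0, 0.0, task)
    out = forward(model, X)
    if task == "regression":
        return float(np.mean((out - Y) ** 2))
    z = out - out.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-np.mean(logp[np.arange(len(Y)), np.asarray(Y, int)]))


def _val_metric(params: dict, X: np.ndarray, Y: np.ndarray, task: str) -> float:
    """Path selection metric, lower is better: MSE, or 1 - accuracy/100."""
    if task == "regression":
        return _val_loss(params, X, Y, task)
    arrs = {k: (v.data if isinstance(v, Tensor) else v) for k, v in params.items()}
    model = _params_to_model(arrs, 0.0, 0.0, task)
    model.task = "classification"
    pred = np.argmax(predict(model, X), axis=1)
    return float(1.0 - np.mean(pred == np.asarray(Y, int)))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for a in range(0, n, batch_size):
        yield perm[a : a + batch_size]


def _check_finite(loss_val: float, lr: float):
    if not np.isfinite(loss_val):
        raise DivergenceError(
            f"training loss is non-finite; try a smaller learning rate than {lr}"
        )


def train_dense(
    X: np.ndarray,
    Y: np.ndarray,
    split: DataSplit,
    config: LassoNetConfig,
    init: dict | None = None,
) -> LassoNetModel:
    """Dense warm start: lambda = 0, no proximal sparsification.

    Mini-batch training of the full multivariate loss with early stopping on
    validation loss (patience in epochs, best parameters restored).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    p = X.shape[1]
    k = Y.shape[1] if config.task == "regression" else int(Y.max()) + 1
    hidden = config.hidden_sizes or _default_hidden(p)
    raw = init if init is not None else init_params(p, k, hidden, config.seed)
    params = _to_tensors(raw)
    plist = list(params.values())
    if config.dense_optimizer == "adam":
        opt = Adam(plist, lr=config.learning_rate)
    else:
        opt = SGD(plist, lr=config.learning_rate, momentum=config.momentum)

    Xtr, Ytr = X[split.train_idx], Y[split.train_idx]
    Xval, Yval = X[split.val_idx], Y[split.val_idx]
    rng = np.random.default_rng(config.seed + 1)

    best_val = np.inf
    best_snapshot = {k_: v.data.copy() for k_, v in params.items()}
    bad_epochs = 0
    for _epoch in range(config.epochs_dense):
        for idx in _batches(len(Xtr), config.batch_size, rng):
            loss = _loss_t(params, Xtr[idx], Ytr[idx], config.task)
            _check_finite(loss.data, config.learning_rate)
            loss.backward()
            opt.step()
        vl = _val_loss(params, Xval, Yval, config.task)
        _check_finite(vl, config.learning_rate)
        if vl < best_val:
            best_val = vl
            best_snapshot = {k_: v.data.copy() for k_, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    return _params_to_model(best_snapshot, config.nu, 0.0, config.task)


def _auto_lambda_start(params: dict, Xtr: np.ndarray, Ytr: np.ndarray,
                       task: str, kill_frac: float = 0.05) -> float:
    """Starting lambda that sparsifies at most ~kill_frac of features.

    At a stationary point of the penalized objective, a theta row is zeroed
    once the magnitude of its loss gradient (evaluated with that row removed)
    drops below lambda. That per-row kill threshold is estimated by a local
    linearization around the dense warm start: |grad| + curvature * |theta|,
    with curvature 2/k for the mean-squared loss on column-standardized
    inputs. lambda_start is the kill_frac-quantile of the row thresholds, so
    the path begins where only the weakest rows are at risk.
    """
    tensors = _to_tensors({k_: np.asarray(v) for k_, v in params.items()})
    loss = _loss_t(tensors, Xtr, Ytr, task)
    loss.backward()
    g = tensors["theta"].grad
    theta = np.asarray(params["theta"])
    k = theta.shape[1]
    curv = (2.0 / k) if task == "regression" else (0.5 / k)
    kill = (np.abs(g) + curv * np.abs(theta)).max(axis=1)
    lam = float(np.quantile(kill, kill_frac))
    return max(lam, 1e-8)


def fit_path(
    X: np.ndarray,
    Y: np.ndarray,
    split: DataSplit,
    config: LassoNetConfig,
    dense_model: LassoNetModel | None = None,
) -> PathResult:
    """Dense-to-sparse regularization path with warm starts.

    Each lambda step runs `epochs_per_step` epochs of SGD(momentum) where
    every gradient step is followed by the hierarchical prox on all feature
    rows; lambda then grows by `path_multiplier` until the support is empty.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y)
    if dense_model is None:
        dense_model = train_dense(X, Y, split, config)
    params = _to_tensors(_model_to_params(dense_model))
    plist = list(params.values())
    lr = config.path_learning_rate
    opt = SGD(plist, lr=lr, momentum=config.momentum)

    Xtr, Ytr = X[split.train_idx], Y[split.train_idx]
    Xval, Yval = X[split.val_idx], Y[split.val_idx]
    rng = np.random.default_rng(config.seed + 2)

    if config.lambda_start == "auto":
        raw = {k_: v.data for k_, v in params.items()}
        lam = _auto_lambda_start(raw, Xtr, Ytr, config.task)
    else:
        lam = float(config.lambda_start)

    points: list[PathPoint] = []
    best_index = -1
    for _step in range(config.max_path_steps):
        for _epoch in range(config.epochs_per_step):
            prev = {k_: v.data.copy() for k_, v in params.items()} if config.tol else None
            for idx in _batches(len(Xtr), config.batch_size, rng):
                loss = _loss_t(params, Xtr[idx], Ytr[idx], config.task)
                _check_finite(loss.data, lr)
                loss.backward()
                opt.step()
                T, W = hier_prox_batch(
                    params["theta"].data, params["W0"].data,
                    lam * lr, config.nu, convention=config.convention,
                )
                params["theta"].data = T
                params["W0"].data = W
            if config.tol is not None:
                delta = max(
                    np.abs(params[k_].data - prev[k_]).max() for k_ in params
                )
                if delta < config.tol:
                    break
        support = int(np.sum(np.abs(params["theta"].data).max(axis=1) > 0))
        vm = _val_metric(params, Xval, Yval, config.task)
        snapshot = _params_to_model(
            {k_: v.data for k_, v in params.items()}, config.nu, lam, config.task
        )
        points.append(PathPoint(lambda_=lam, model=snapshot,
                                val_metric=vm, support_size=support))
        if support == 0:
            break
        lam *= config.path_multiplier

    best_index = _best_index(points)
    return PathResult(points=points, best_index=best_index)


def _best_index(points: list) -> int:
    best = 0
    for i in range(1, len(points)):
        pt, bpt = points[i], points[best]
        if pt.val_metric < bpt.val_metric or (
            pt.val_metric == bpt.val_metric and pt.support_size < bpt.support_size
        ):
            best = i
    return best


def select_model(path: PathResult) -> PathPoint:
    """Validation-optimal path point; ties broken toward smaller support."""
    if not path.points:
        raise ValueError("empty regularization path")
    return path.points[_best_index(path.points)]


def selected_features(model: LassoNetModel, marker_ids=None,
                      trait_names=None) -> SelectionReport:
    """Per-trait (marker, coefficient) pairs with nonzero skip coefficient."""
    p, k = model.theta.shape
    if marker_ids is None:
        marker_ids = [f"M{j}" for j in range(p)]
    if trait_names is None:
        trait_names = [f"trait_{t}" for t in range(k)]
    per_trait = {}
    for t in range(k):
        nz = np.flatnonzero(model.theta[:, t] != 0.0)
        per_trait[trait_names[t]] = [
            (marker_ids[j], float(model.theta[j, t])) for j in nz
        ]
    return SelectionReport(per_trait=per_trait)
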