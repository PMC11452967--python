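"""GANDALF: stacked Gated Feature Learning Units with sparse feature masks.

Each GFLU stage n applies a learnable soft feature-selection mask
M_n = t-softmax(logits_n, t_n) to the raw input (X_n = M_n * X), then updates
a d-dimensional stage representation phi with GRU-style gates:

    z_n    = sigmoid(Wz . [phi_{n-1}; X_n])        update gate
    r_n    = sigmoid(Wr . [phi_{n-1}; X_n])        reset gate
    cand_n = tanh(Wo . [r_n * phi_{n-1}; X_n])     candidate representation
    phi_n  = (1 - z_n) * phi_{n-1} + z_n * cand_n

The initial representation phi_0 is a learned linear projection of the
stage-1 masked input. The final representation feeds a small MLP head with k
outputs (trait predictions or class logits). The t-softmax is implemented as
a temperature-scaled softmax whose entries below 1e-6 of the maximum are
clipped to exact zero and renormalized, emulating sparse selection while
keeping the simplex property exactly; the temperature is a learnable
per-stage parameter kept positive through a softplus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, cross_entropy, mse_loss
from .simdata import DataSplit

__all__ = [
    "GandalfConfig",
    "GFLUParams",
    "GandalfModel",
    "t_softmax",
    "gflu_step",
    "fit_gandalf",
    "predict_gandalf",
]

_CLIP = 1e-6  # mask entries below _CLIP * max are zeroed then renormalized


class DivergenceError(RuntimeError):
    pass


@dataclass
class GandalfConfig:
    n_stages: int = 4
    dim: int = 64  # stage representation dimension d
    head_hidden: tuple = (32,)
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 20
    seed: int = 0
    task: str = "regression"
    init_temperature: float = 1.0

    def __post_init__(self):
        if self.n_stages < 0:
            raise ValueError("n_stages must be >= 0")
        if self.init_temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class GFLUParams:
    mask_logits: np.ndarray  # (p,)
    temperature_raw: float  # softplus(raw) = t > 0
    update_gate_weights: tuple  # (W (d, d+p), b (d,))
    reset_gate_weights: tuple
    candidate_weights: tuple

    @property
    def temperature(self) -> float:
        return float(np.logaddexp(0.0, self.temperature_raw))


@dataclass
class GandalfModel:
    stages: list  # list[GFLUParams]
    proj: tuple  # phi_0 projection: (W (p, d), b (d,)); None when 0 stages
    head: list  # [(W, b), ...] MLP head ending in k outputs
    task: str = "regression"
    config: GandalfConfig = field(default_factory=GandalfConfig)

    def masks(self) -> np.ndarray:
        """Per-stage feature masks (n_stages x p), each on the simplex."""
        return np.stack(
            [t_softmax(s.mask_logits, s.temperature) for s in self.stages]
        ) if self.stages else np.zeros((0, 0))


# ---------------------------------------------------------------------------
# numpy reference forward pieces (unit-testable, no autodiff)
# ---------------------------------------------------------------------------


def t_softmax(logits: np.ndarray, t: float) -> np.ndarray:
    """Temperature-scaled softmax with hard-zero clipping; sums to exactly 1."""
    if t <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(logits, float) / t
    z = z - z.max()
    m = np.exp(z)
    m = m / m.sum()
    m[m < _CLIP * m.max()] = 0.0
    return m / m.sum()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def gflu_step(phi_prev: np.ndarray, X_row: np.ndarray, stage: GFLUParams) -> np.ndarray:
    """One GFLU update for a single sample (reference implementation)."""
    mask = t_softmax(stage.mask_logits, stage.temperature)
    xn = mask * np.asarray(X_row, float)
    phi_prev = np.asarray(phi_prev, float)
    cat = np.concatenate([phi_prev, xn])
    Wz, bz = stage.update_gate_weights
    Wr, br = stage.reset_gate_weights
    Wo, bo = stage.candidate_weights
    z = _sigmoid(cat @ Wz + bz)
    r = _sigmoid(cat @ Wr + br)
    cand = np.tanh(np.concatenate([r * phi_prev, xn]) @ Wo + bo)
    return (1.0 - z) * phi_prev + z * cand


# ---------------------------------------------------------------------------
# autodiff training graph
# ---------------------------------------------------------------------------


def _init_gandalf_params(p: int, k: int, config: GandalfConfig) -> dict:
    rng = np.random.default_rng(config.seed)
    d = config.dim
    t_raw = float(np.log(np.expm1(config.init_temperature)))  # softplus inverse
    params = {}
    if config.n_stages > 0:
        params["proj_W"] = rng.normal(0, np.sqrt(1.0 / p), size=(p, d))
        params["proj_b"] = np.zeros(d)
    for n in range(config.n_stages):
        params[f"logits{n}"] = np.zeros(p)
        params[f"traw{n}"] = np.array(t_raw)
        for gate in ("z", "r", "o"):
            params[f"W{gate}{n}"] = rng.normal(0, np.sqrt(1.0 / (d + p)), size=(d + p, d))
            params[f"b{gate}{n}"] = np.zeros(d)
    in_dim = d if config.n_stages > 0 else p
    dims = [in_dim, *config.head_hidden, k]
    for li in range(len(dims) - 1):
        params[f"headW{li}"] = rng.normal(0, np.sqrt(2.0 / dims[li]), size=(dims[li], dims[li + 1]))
        params[f"headb{li}"] = np.zeros(dims[li + 1])
    return params


def _tsoftmax_graph(logits: Tensor, traw: Tensor) -> Tensor:
    """t-softmax as an autodiff graph over (logits, raw temperature)."""
    # t = softplus(traw) built from primitives: log(1+exp) via sigmoid trick:
    # softplus'(x) = sigmoid(x); represent t with a custom tensor
    t = _softplus(traw)
    inv_t = _reciprocal(t)
    scaled = logits * inv_t  # broadcast scalar
    # row vector softmax via log_softmax on shape (1, p)
    row = _reshape_row(scaled)
    m = row.log_softmax().exp()
    keep = (m.data >= _CLIP * m.data.max()).astype(float)  # constant support
    mk = m * Tensor(keep)
    denom = mk.sum()
    return mk * _reciprocal(denom)


def _softplus(x: Tensor) -> Tensor:
    out_data = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def bwd(g):
        x._accum(g * sig)

    return x._make(out_data, (x,), bwd)


def _reciprocal(x: Tensor) -> Tensor:
    out_data = 1.0 / x.data

    def bwd(g):
        x._accum(-g * out_data**2)

    return x._make(out_data, (x,), bwd)


def _reshape_row(x: Tensor) -> Tensor:
    out_data = x.data.reshape(1, -1)

    def bwd(g):
        x._accum(g.reshape(x.data.shape))

    return x._make(out_data, (x,), bwd)


def _reshape_flat(x: Tensor) -> Tensor:
    out_data = x.data.reshape(-1)

    def bwd(g):
        x._accum(g.reshape(x.data.shape))

    return x._make(out_data, (x,), bwd)


def _forward_gandalf(params: dict, X: Tensor, config: GandalfConfig) -> Tensor:
    n_stages = config.n_stages
    if n_stages > 0:
        mask0 = _reshape_row(_reshape_flat(_tsoftmax_graph(params["logits0"], params["traw0"])))
        phi = (X * mask0) @ params["proj_W"] + params["proj_b"]
        for n in range(n_stages):
            mask = _reshape_row(_reshape_flat(_tsoftmax_graph(params[f"logits{n}"], params[f"traw{n}"])))
            xn = X * mask
            cat = concat([phi, xn], axis=1)
            z = (cat @ params[f"Wz{n}"] + params[f"bz{n}"]).sigmoid()
            r = (cat @ params[f"Wr{n}"] + params[f"br{n}"]).sigmoid()
            cand = (concat([r * phi, xn], axis=1) @ params[f"Wo{n}"] + params[f"bo{n}"]).tanh()
            phi = (Tensor(np.array(1.0)) - z) * phi + z * cand
        h = phi
    else:
        h = X
    li = 0
    while f"headW{li}" in params:
        h = h @ params[f"headW{li}"] + params[f"headb{li}"]
        if f"headW{li + 1}" in params:
            h = h.relu()
        li += 1
    return h


def _params_to_model(params: dict, config: GandalfConfig) -> GandalfModel:
    get = lambda k: params[k].data if isinstance(params[k], Tensor) else params[k]
    stages = []
    for n in range(config.n_stages):
        stages.append(
            GFLUParams(
                mask_logits=get(f"logits{n}").copy(),
                temperature_raw=float(get(f"traw{n}")),
                update_gate_weights=(get(f"Wz{n}").copy(), get(f"bz{n}").copy()),
                reset_gate_weights=(get(f"Wr{n}").copy(), get(f"br{n}").copy()),
                candidate_weights=(get(f"Wo{n}").copy(), get(f"bo{n}").copy()),
            )
        )
    proj = (get("proj_W").copy(), get("proj_b").copy()) if config.n_stages > 0 else None
    head = []
    li = 0
    while f"headW{li}" in params:
        head.append((get(f"headW{li}").copy(), get(f"headb{li}").copy()))
        li += 1
    return GandalfModel(stages=stages, proj=proj, head=head, task=config.task,
                        config=config)


def predict_gandalf(model: GandalfModel, X: np.ndarray) -> np.ndarray:
    """Trait predictions (regression) or class probabilities (classification)."""
    X = np.asarray(X, float)
    if model.stages:
        mask0 = t_softmax(model.stages[0].mask_logits, model.stages[0].temperature)
        W0, b0 = model.proj
        phi = (X * mask0) @ W0 + b0
        for stage in model.stages:
            mask = t_softmax(stage.mask_logits, stage.temperature)
            xn = X * mask
            cat = np.concatenate([phi, xn], axis=1)
            Wz, bz = stage.update_gate_weights
            Wr, br = stage.reset_gate_weights
            Wo, bo = stage.candidate_weights
            z = _sigmoid(cat @ Wz + bz)
            r = _sigmoid(cat @ Wr + br)
            cand = np.tanh(np.concatenate([r * phi, xn], axis=1) @ Wo + bo)
            phi = (1.0 - z) * phi + z * cand
        h = phi
    else:
        h = X
    for i, (W, b) in enumerate(model.head):
        h = h @ W + b
        if i < len(model.head) - 1:
            h = np.maximum(h, 0.0)
    if model.task == "regression":
        return h
    zz = h - h.max(axis=1, keepdims=True)
    e = np.exp(zz)
    return e / e.sum(axis=1, keepdims=True)


def fit_gandalf(
    X: np.ndarray,
    Y: np.ndarray,
    split: DataSplit,
    config: GandalfConfig,
) -> GandalfModel:
    """End-to-end Adam training of masks, gates and head; early stopping."""
    X = np.asarray(X, float)
    Y = np.asarray(Y)
    p = X.shape[1]
    k = Y.shape[1] if config.task == "regression" else int(Y.max()) + 1
    raw = _init_gandalf_params(p, k, config)
    params = {key: Tensor(val.copy() if isinstance(val, np.ndarray) else np.array(val),
                          requires_grad=True) for key, val in raw.items()}
    opt = Adam(list(params.values()), lr=config.learning_rate)

    Xtr, Ytr = X[split.train_idx], Y[split.train_idx]
    Xval, Yval = X[split.val_idx], Y[split.val_idx]
    rng = np.random.default_rng(config.seed + 1)

    def loss_of(Xb, Yb):
        out = _forward_gandalf(params, Tensor(Xb), config)
        return mse_loss(out, Yb) if config.task == "regression" else cross_entropy(out, Yb)

    best_val = np.inf
    best = {key: v.data.copy() for key, v in params.items()}
    bad = 0
    n = len(Xtr)
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        for a in range(0, n, config.batch_size):
            idx = perm[a : a + config.batch_size]
            loss = loss_of(Xtr[idx], Ytr[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"loss diverged at learning rate {config.learning_rate}"
                )
            loss.backward()
            opt.step()
        vl = float(loss_of(Xval, Yval).data)
        if vl < best_val:
            best_val = vl
            best = {key: v.data.copy() for key, v in params.items()}
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    return _params_to_model(best, config)
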