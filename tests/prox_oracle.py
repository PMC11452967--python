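"""Independent brute-force oracle for the hierarchical proximal operator.

Solves, for a single feature row,

    min_{theta, W}  1/2 ||theta - b||^2 + 1/2 ||W - v||^2 + lam * pen(theta)
    s.t.            ||W||_inf <= nu * sel(theta)

by a global grid search over s = sel(theta) followed by a bounded 1-D
polish, using closed-form inner minimizers for fixed s. This shares no code
with the production solver (which uses a sorted-breakpoint search over the
piecewise-quadratic stationarity conditions).

Conventions:
  elementwise: pen(theta) = sum_t |theta_t|,  sel(theta) = max_t |theta_t|
  group:       pen(theta) = sel(theta) = ||theta||_2
"""

import numpy as np
from scipy.optimize import minimize_scalar


def objective(theta, W, b, v, lam, convention):
    theta = np.asarray(theta, float)
    if convention == "elementwise":
        pen = np.abs(theta).sum()
    else:
        pen = np.linalg.norm(theta)
    return (
        0.5 * np.sum((theta - b) ** 2)
        + 0.5 * np.sum((np.asarray(W, float) - v) ** 2)
        + lam * pen
    )


def feasible(theta, W, nu, convention, tol=1e-9):
    if convention == "elementwise":
        sel = np.abs(theta).max() if np.size(theta) else 0.0
    else:
        sel = np.linalg.norm(theta)
    bound = np.inf if np.isinf(nu) else nu * sel
    return np.abs(W).max() <= bound + tol if np.size(W) else True


def _cost_at_s(s, b, v, lam, nu, convention):
    """Vectorized g(s): minimal objective with sel(theta) = s exactly."""
    s = np.atleast_1d(np.asarray(s, float))
    if np.isinf(nu):
        w_cost = np.zeros_like(s)
    else:
        excess = np.maximum(np.abs(v)[None, :] - nu * s[:, None], 0.0)
        w_cost = 0.5 * (excess**2).sum(axis=1)
    if convention == "group":
        nb = np.linalg.norm(b)
        th_cost = 0.5 * (s - nb) ** 2 + lam * s
        return th_cost + w_cost
    soft = np.maximum(np.abs(b) - lam, 0.0)
    u = np.minimum(soft[None, :], s[:, None])  # clipped magnitudes
    h = 0.5 * (u - np.abs(b)[None, :]) ** 2 + lam * u
    base = h.sum(axis=1)
    # if no coordinate reaches s, the cheapest coordinate is raised to s
    raised = 0.5 * (s[:, None] - np.abs(b)[None, :]) ** 2 + lam * s[:, None]
    extra = np.min(raised - h, axis=1)
    need = soft.max() < s
    return base + np.where(need, extra, 0.0) + w_cost


def _params_at_s(s, b, v, lam, nu, convention):
    if np.isinf(nu):
        W = np.asarray(v, float).copy()
    else:
        W = np.clip(v, -nu * s, nu * s)
    if convention == "group":
        nb = np.linalg.norm(b)
        theta = s * b / nb if nb > 0 else np.zeros_like(b)
        return theta, W
    soft = np.maximum(np.abs(b) - lam, 0.0)
    u = np.minimum(soft, s)
    if soft.max() < s:
        raised = 0.5 * (s - np.abs(b)) ** 2 + lam * s
        h = 0.5 * (u - np.abs(b)) ** 2 + lam * u
        u = u.copy()
        u[np.argmin(raised - h)] = s
    return np.sign(b) * u, W


def brute_prox(b, v, lam, nu, convention="elementwise"):
    """Globally minimize over s by dense grid + bounded scalar polish."""
    b = np.asarray(b, float)
    v = np.asarray(v, float)
    b_reach = np.linalg.norm(b) if convention == "group" else np.abs(b).max()
    if nu == 0:
        hi = max(b_reach, 1.0)
    else:
        hi = max(b_reach, (np.abs(v).max() / nu if not np.isinf(nu) else 0.0))
    s_grid = np.linspace(0.0, hi + 1.0, 4001)
    costs = _cost_at_s(s_grid, b, v, lam, nu, convention)
    i = int(np.argmin(costs))
    lo = s_grid[max(i - 1, 0)]
    hi = s_grid[min(i + 1, len(s_grid) - 1)]
    res = minimize_scalar(
        lambda s: float(_cost_at_s(s, b, v, lam, nu, convention)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-13},
    )
    s_star = float(res.x)
    if float(_cost_at_s(0.0, b, v, lam, nu, convention)[0]) <= res.fun:
        s_star = 0.0
    theta, W = _params_at_s(s_star, b, v, lam, nu, convention)
    return theta, W, float(_cost_at_s(s_star, b, v, lam, nu, convention)[0])
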