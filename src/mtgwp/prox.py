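"""Hierarchical proximal operator for multi-task LassoNet.

For each input feature i the model carries a skip-connection coefficient row
theta_i (one entry per trait/task) and a first-hidden-layer weight row W_i.
After a gradient step lands at (b, v), the proximal step solves exactly

    min_{theta, W}  1/2 ||theta - b||^2 + 1/2 ||W - v||^2 + lam * pen(theta)
    subject to      ||W||_inf <= nu * sel(theta)

with two conventions for the multi-task penalty/selection magnitude:

* ``elementwise`` (default): pen = sum_t |theta_t|,  sel = max_t |theta_t|
* ``group``:                 pen = sel = ||theta||_2

Both reduce to a one-dimensional convex piecewise-quadratic problem in the
selection magnitude s = sel(theta): for fixed s the optimal W clamps v to
[-nu*s, nu*s] and each |theta_t| is the soft-thresholded value capped at s,
with (at most) the largest-|b| coordinate raised to s when the cap binds.
The minimizer over s is found exactly by sorting the breakpoints
{soft(|b_t|), |v_j|/nu} and solving the linear derivative on the active
segment — O((h+k) log(h+k)) per feature row, vectorized over all p rows.

With nu = 0 the constraint forces W = 0 and theta is plain soft-thresholding
(the Lasso limit); nu = inf drops the constraint entirely (unregularized
network limit, up to the L1 penalty on theta).
"""

from __future__ import annotations

import numpy as np

__all__ = ["hier_prox", "hier_prox_batch"]


def _soft(x: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - lam, 0.0)


def hier_prox_batch(
    B: np.ndarray,
    V: np.ndarray,
    lam: float,
    nu: float,
    convention: str = "elementwise",
):
    """Apply the hierarchical prox to every feature row simultaneously.

    Parameters
    ----------
    B : (p, k) post-gradient skip coefficients.
    V : (p, h) post-gradient first-layer weights.
    lam : nonnegative penalty step (learning-rate-scaled lambda).
    nu : hierarchy coefficient; 0 gives the Lasso, ``np.inf`` no constraint.

    Returns
    -------
    (Theta, W) of the same shapes, satisfying the hierarchy constraint
    exactly; a zero theta row forces a zero W row (for finite nu).
    """
    if lam < 0 or nu < 0:
        raise ValueError("lam and nu must be nonnegative")
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))

    if np.isinf(nu):
        return _soft(B, lam), V.copy()
    if nu == 0.0:
        return _soft(B, lam), np.zeros_like(V)

    if convention == "group":
        beta = np.linalg.norm(B, axis=1, keepdims=True)  # (p, 1)
    elif convention == "elementwise":
        beta = np.abs(B)  # (p, k)
    else:
        raise ValueError(f"unknown convention {convention!r}")

    p, k = beta.shape
    a = np.abs(V)  # (p, h)
    soft = np.maximum(beta - lam, 0.0)  # (p, k)
    maxsoft = soft.max(axis=1)  # (p,)
    beta_star = beta.max(axis=1)  # (p,)

    # breakpoints of the 1-D derivative, with per-point (slope, intercept)
    # contributions active while s < breakpoint
    pts = np.concatenate([soft, a / nu], axis=1)  # (p, m)
    slopes = np.concatenate(
        [np.ones_like(soft), np.full_like(a, nu * nu)], axis=1
    )
    intercepts = np.concatenate([lam - beta, -nu * a], axis=1)

    order = np.argsort(pts, axis=1)
    pts_s = np.take_along_axis(pts, order, axis=1)
    slo_s = np.take_along_axis(slopes, order, axis=1)
    int_s = np.take_along_axis(intercepts, order, axis=1)

    # suffix sums: S[:, i] = contributions of points sorted-index >= i
    zcol = np.zeros((p, 1))
    S = np.concatenate([np.cumsum(slo_s[:, ::-1], axis=1)[:, ::-1], zcol], 1)
    I = np.concatenate([np.cumsum(int_s[:, ::-1], axis=1)[:, ::-1], zcol], 1)

    # interval i = (L_i, U_i); the "raise" term (pushing the largest-|b|
    # coordinate up to s) is active once the interval lies above maxsoft
    L = np.concatenate([zcol, pts_s], axis=1)  # (p, m+1)
    U = np.concatenate([pts_s, np.full((p, 1), np.inf)], axis=1)
    raise_on = L >= maxsoft[:, None]
    S = S + raise_on
    I = I + raise_on * (lam - beta_star)[:, None]

    # first non-degenerate interval whose upper-end derivative is >= 0 holds
    # the minimizer (zero-width intervals, e.g. repeated breakpoints at 0,
    # carry contributions that are never active for s > L and must be skipped)
    phi_up = S * U + I
    phi_up[:, -1] = np.inf
    phi_up[U <= L] = -np.inf
    i0 = np.argmax(phi_up >= 0.0, axis=1)
    rows = np.arange(p)
    S0, I0 = S[rows, i0], I[rows, i0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s_star = np.where(S0 > 0, -I0 / np.where(S0 > 0, S0, 1.0), L[rows, i0])
    s_star = np.clip(s_star, L[rows, i0], np.minimum(U[rows, i0], np.inf))
    s_star = np.maximum(s_star, 0.0)

    # reconstruct theta magnitudes: cap at s*, raising argmax-|b| when needed
    u = np.minimum(soft, s_star[:, None])
    tstar = np.argmax(beta, axis=1)
    lift = s_star > maxsoft
    u[rows[lift], tstar[lift]] = s_star[lift]

    W = np.sign(V) * np.minimum(a, (nu * s_star)[:, None])

    if convention == "group":
        norms = np.linalg.norm(B, axis=1)
        dirs = np.zeros_like(B)
        nz = norms > 0
        dirs[nz] = B[nz] / norms[nz, None]
        dirs[~nz, 0] = 1.0  # arbitrary direction for a zero row
        Theta = dirs * u[:, [0]]
    else:
        sgn = np.where(B == 0.0, 1.0, np.sign(B))
        Theta = sgn * u
    return Theta, W


def hier_prox(theta_row, w_row, lambda_step: float, nu: float,
              convention: str = "elementwise"):
    """Single-row convenience wrapper around :func:`hier_prox_batch`."""
    b = np.asarray(theta_row, dtype=np.float64).reshape(1, -1)
    v = np.asarray(w_row, dtype=np.float64).reshape(1, -1)
    T, W = hier_prox_batch(b, v, lambda_step, nu, convention=convention)
    return T[0], W[0]
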