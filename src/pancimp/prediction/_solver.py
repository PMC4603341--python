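"""Proximal-gradient solvers for L1- and group-penalized logistic regression.

Single-task objective (features standardized, intercept unpenalized):

    F(w, c) = sum_i s_i log(1 + exp(-y_i (x_i·w + u_i·c))) + lam * ||w||_1

with sample weights s summing to 1 (default 1/n) and an unpenalized
intercept block U (one column of ones, or a per-tissue one-hot for combined
fits).

Multi-task (group-lasso) objective over T tasks with per-task coefficients
W[:, t] and intercepts b[t]:

    F(W, b) = sum_t (1/(T n_t)) sum_i log(1 + exp(-y_ti (x_ti·W_t + b_t)))
              + lam * sqrt(T) * sum_g ||W[g, :]||_2

A gene is selected when its coefficient (group row norm) exceeds 1e-8.
Both solvers use FISTA with an exact spectral Lipschitz bound and monotone
(function-value) restarts, so the objective never increases across
iterations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SELECT_TOL = 1e-8


class ConvergenceError(RuntimeError):
    pass


def _log1pexp(z):
    # numerically stable log(1 + exp(z))
    out = np.empty_like(z)
    pos = z > 0
    out[pos] = z[pos] + np.log1p(np.exp(-z[pos]))
    out[~pos] = np.log1p(np.exp(z[~pos]))
    return out


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_threshold(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def group_soft_threshold(W, thr):
    """Row-wise group soft-thresholding of a (p, T) matrix."""
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    scale = np.maximum(1.0 - thr / np.maximum(norms, 1e-300), 0.0)
    return W * scale


@dataclass
class SolverInfo:
    objective: float
    n_iter: int
    converged: bool
    grad_map_norm: float


def lasso_lambda_max(X, y_sign, sample_weight, U):
    """Smallest lam at which the all-zero coefficient vector is optimal
    (intercepts at the weighted class log-odds per intercept group)."""
    c = _null_intercepts(y_sign, sample_weight, U)
    z = U @ c
    g = -(y_sign * _sigmoid(-y_sign * z)) * sample_weight
    return float(np.max(np.abs(X.T @ g)))


def _null_intercepts(y_sign, s, U):
    c = np.zeros(U.shape[1])
    y01 = (y_sign > 0).astype(float)
    for j in range(U.shape[1]):
        m = U[:, j] > 0
        p = np.clip(np.average(y01[m], weights=s[m]), 1e-12, 1 - 1e-12)
        c[j] = np.log(p / (1 - p))
    return c


def fit_lasso_path(X, y_sign, lams, sample_weight=None, U=None,
                   max_iter=5000, tol=1e-7, strict=True):
    """Warm-started lasso-logistic fits along a decreasing lam path.

    Returns a list of ``(w, c, SolverInfo)`` in the order of ``lams``.
    """
    n, p = X.shape
    s = np.full(n, 1.0 / n) if sample_weight is None else sample_weight / sample_weight.sum()
    if U is None:
        U = np.ones((n, 1))
    A = np.hstack([X, U]) * np.sqrt(s)[:, None]
    L = 0.25 * np.linalg.norm(A, 2) ** 2
    L = max(L, 1e-12)

    def objective(w, c):
        z = X @ w + U @ c
        return float(np.sum(s * _log1pexp(-y_sign * z)))

    def gradient(w, c):
        z = X @ w + U @ c
        g = -(y_sign * _sigmoid(-y_sign * z)) * s
        return X.T @ g, U.T @ g

    w = np.zeros(p)
    c = _null_intercepts(y_sign, s, U)
    out = []
    for lam in lams:
        w, c, info = _fista(w, c, objective, gradient, L, lam,
                            prox=lambda v, t: soft_threshold(v, t),
                            pen=lambda v: np.abs(v).sum(),
                            max_iter=max_iter, tol=tol,
                            strict=strict and lam > 0)
        out.append((w.copy(), c.copy(), info))
    return out


def group_lambda_max(Xs, ys_sign, weights):
    """Group-wise lam_max: max_g ||stacked per-task null gradients||_2 / sqrt(T)."""
    T = len(Xs)
    grads = []
    for X, y, wt in zip(Xs, ys_sign, weights):
        p0 = np.clip(np.mean(y > 0), 1e-12, 1 - 1e-12)
        b = np.log(p0 / (1 - p0))
        g = -(y * _sigmoid(-y * np.full(len(y), b))) * wt
        grads.append(X.T @ g)
    G = np.column_stack(grads)  # p × T
    return float(np.max(np.linalg.norm(G, axis=1)) / np.sqrt(T))


def fit_group_lasso_path(Xs, ys_sign, lams, max_iter=5000, tol=1e-7, strict=True):
    """Warm-started multi-task group-lasso logistic fits along a lam path.

    ``Xs``/``ys_sign`` are per-task design matrices (n_t × p) and ±1 labels.
    Returns a list of ``(W, b, SolverInfo)`` with W of shape (p, T).
    """
    T = len(Xs)
    p = Xs[0].shape[1]
    if any(X.shape[1] != p for X in Xs):
        raise ValueError("all tasks must share the same gene universe")
    weights = [np.full(len(y), 1.0 / (T * len(y))) for y in ys_sign]
    L = 0.25 * sum(
        np.linalg.norm(X * np.sqrt(wt)[:, None], 2) ** 2
        for X, wt in zip(Xs, weights)
    )
    L = max(L, 1e-12)
    sqrtT = np.sqrt(T)

    def objective(W, b):
        tot = 0.0
        for t in range(T):
            z = Xs[t] @ W[:, t] + b[t]
            tot += float(np.sum(weights[t] * _log1pexp(-ys_sign[t] * z)))
        return tot

    def gradient(W, b):
        gW = np.empty_like(W)
        gb = np.empty(T)
        for t in range(T):
            z = Xs[t] @ W[:, t] + b[t]
            g = -(ys_sign[t] * _sigmoid(-ys_sign[t] * z)) * weights[t]
            gW[:, t] = Xs[t].T @ g
            gb[t] = g.sum()
        return gW, gb

    W = np.zeros((p, T))
    b = np.array([
        np.log(np.clip(np.mean(y > 0), 1e-12, 1 - 1e-12)
               / np.clip(np.mean(y < 0), 1e-12, 1 - 1e-12))
        for y in ys_sign
    ])
    out = []
    for lam in lams:
        W, b, info = _fista(W, b, objective, gradient, L, lam * sqrtT,
                            prox=group_soft_threshold,
                            pen=lambda V: np.linalg.norm(V, axis=1).sum(),
                            max_iter=max_iter, tol=tol,
                            strict=strict and lam > 0)
        out.append((W.copy(), b.copy(), info))
    return out


def _fista(w0, c0, objective, gradient, L, lam, prox, pen, max_iter, tol,
           strict=True):
    """FISTA with exact Lipschitz step 1/L and monotone restart.

    ``w0`` is the penalized block (vector or matrix), ``c0`` the unpenalized
    intercept block.  ``prox(v, thr)`` applies the penalty's proximal map.
    With ``strict=False`` hitting the iteration cap returns the capped
    solution instead of raising (used for unpenalized, possibly separable
    fits whose coefficients diverge by design).
    """
    w, c = w0.copy(), np.atleast_1d(np.asarray(c0, dtype=float)).copy()
    vw, vc = w.copy(), c.copy()  # extrapolation point
    tk = 1.0
    F = objective(w, c) + lam * pen(w)
    step = 1.0 / L
    converged = False
    grad_map = np.inf
    for it in range(1, max_iter + 1):
        gw, gc = gradient(vw, vc)
        w_new = prox(vw - step * gw, lam * step)
        c_new = vc - step * gc
        F_new = objective(w_new, c_new) + lam * pen(w_new)
        if F_new > F:  # monotone restart: plain proximal step from (w, c)
            gw, gc = gradient(w, c)
            w_new = prox(w - step * gw, lam * step)
            c_new = c - step * gc
            F_new = objective(w_new, c_new) + lam * pen(w_new)
            tk = 1.0
        grad_map = float(
            np.sqrt(np.sum((w_new - w) ** 2) + np.sum((c_new - c) ** 2)) / step
        )
        rel = abs(F - F_new) / max(abs(F), 1e-12)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk ** 2))
        mom = (tk - 1.0) / t_next
        vw = w_new + mom * (w_new - w)
        vc = c_new + mom * (c_new - c)
        w, c, F, tk = w_new, c_new, F_new, t_next
        if rel < tol:
            converged = True
            break
    if not converged and strict:
        raise ConvergenceError(
            f"proximal gradient did not converge in {max_iter} iterations "
            f"(lam={lam:.3g}, objective={F:.6g}, grad_map={grad_map:.3g})"
        )
    return w, c, SolverInfo(objective=F, n_iter=it, converged=converged,
                            grad_map_norm=grad_map)


def lambda_grid(lam_max, n_lambdas=50, min_ratio=0.01):
    """Log-spaced penalty grid from lam_max down to min_ratio·lam_max."""
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)
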