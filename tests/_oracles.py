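"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (loops, BFS, enumeration, small QP
solves) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        manhattan = sum(abs(x) for x in d)
        if connectivity == 6 and manhattan > 1:
            continue
        if connectivity == 18 and manhattan > 2:
            continue
        offs.append(d)
    return offs


def flood_fill_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS connected-component labeling of a boolean volume."""
    offs = neighbor_offsets(connectivity)
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (
                    0 <= w[0] < shape[0]
                    and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and mask[w]
                    and not labels[w]
                ):
                    labels[w] = current
                    stack.append(w)
    return labels, current


def n_components(mask: np.ndarray, connectivity: int = 26) -> int:
    return flood_fill_label(mask, connectivity)[1]


def exact_mannwhitney_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0  # no ties expected in tests
    obs = ranks[:n_a].sum()
    stats = []
    for comb in itertools.combinations(range(len(pooled)), n_a):
        stats.append(ranks[list(comb)].sum())
    stats = np.asarray(stats)
    mu = stats.mean()
    return float((np.abs(stats - mu) >= abs(obs - mu) - 1e-12).mean())


def ols_residuals_2x2(X: np.ndarray, y: np.ndarray, v: np.ndarray):
    """Closed-form OLS residuals on [1, v] via hand-rolled 2x2 inversion."""
    n = len(v)
    D = np.column_stack([np.ones(n), v])
    G = D.T @ D
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    Ginv = np.array([[G[1, 1], -G[0, 1]], [-G[1, 0], G[0, 0]]]) / det
    H = D @ Ginv @ D.T
    return X - H @ X, y - H @ y


def primal_linear_svr(X: np.ndarray, y: np.ndarray, C: float, epsilon: float):
    """Directly solve the linear epsilon-SVR primal QP (SLSQP).

    min 0.5||w||^2 + C sum(xi+ + xi-)
    s.t. |y - (Xw + b)| <= epsilon + xi, xi >= 0.
    """
    n, d = X.shape

    def unpack(z):
        return z[:d], z[d], z[d + 1 : d + 1 + n], z[d + 1 + n :]

    def fun(z):
        w, _b, xp, xm = unpack(z)
        return 0.5 * w @ w + C * (xp.sum() + xm.sum())

    def jac(z):
        w = z[:d]
        return np.concatenate([w, [0.0], np.full(2 * n, C)])

    cons = [
        {"type": "ineq",
         "fun": lambda z: epsilon + unpack(z)[2] - (y - (X @ unpack(z)[0] + unpack(z)[1]))},
        {"type": "ineq",
         "fun": lambda z: epsilon + unpack(z)[3] - ((X @ unpack(z)[0] + unpack(z)[1]) - y)},
    ]
    bounds = [(None, None)] * (d + 1) + [(0, None)] * (2 * n)
    # feasible start: w = 0, b = median(y), slacks = constraint violations
    b0 = float(np.median(y))
    xp0 = np.maximum(0.0, (y - b0) - epsilon)
    xm0 = np.maximum(0.0, (b0 - y) - epsilon)
    z0 = np.concatenate([np.zeros(d), [b0], xp0, xm0])
    best = None
    for ftol in (1e-16, 1e-14, 1e-12):
        res = minimize(
            fun, z0, jac=jac, constraints=cons, bounds=bounds,
            method="SLSQP", options={"maxiter": 2000, "ftol": ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        z0 = res.x  # warm restart at a looser tolerance
    assert best is not None
    return best.x[:d], best.x[d]


def svr_dual_objective(alpha: np.ndarray, K: np.ndarray, y: np.ndarray,
                       epsilon: float) -> float:
    return float(y @ alpha - 0.5 * alpha @ K @ alpha - epsilon * np.abs(alpha).sum())


def best_dual_on_lattice(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                         steps: int = 9) -> float:
    """Best epsilon-SVR dual objective over a coarse alpha lattice.

    Enumerates alpha_1..alpha_{n-1} on a grid in [-C, C] and sets
    alpha_n = -sum (equality constraint), skipping infeasible points.
    """
    n = len(y)
    grid = np.linspace(-C, C, steps)
    best = -np.inf
    for combo in itertools.product(grid, repeat=n - 1):
        last = -sum(combo)
        if abs(last) > C + 1e-12:
            continue
        alpha = np.array(list(combo) + [last])
        best = max(best, svr_dual_objective(alpha, K, y, epsilon))
    return best
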