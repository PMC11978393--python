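"""Independent reference solvers used to cross-check the package.

These deliberately share no code path with the package implementations:
the fused-graphical-lasso oracle minimizes a huberized (smoothed-l1)
version of the objective with L-BFGS over upper-triangle parameters, and
the scalar mean-test oracle recomputes the ridge Hotelling form from first
principles with plain arithmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

MU = 1e-8  # l1 smoothing; objective error is O(MU * #terms)


def _unpack(vec: np.ndarray, p: int, G: int) -> list[np.ndarray]:
    iu = np.triu_indices(p)
    k = iu[0].size
    mats = []
    for g in range(G):
        M = np.zeros((p, p))
        M[iu] = vec[g * k : (g + 1) * k]
        M = M + M.T - np.diag(np.diag(M))
        mats.append(M)
    return mats


def _smooth_abs(x: np.ndarray) -> float:
    return float(np.sum(np.sqrt(x * x + MU * MU) - MU))


def fgl_objective_oracle(
    Thetas: list[np.ndarray],
    covariances: list[np.ndarray],
    lambda1: float,
    lambda2: float,
) -> float:
    total = 0.0
    G = len(Thetas)
    for T, S in zip(Thetas, covariances):
        evals = np.linalg.eigvalsh(T)
        if evals[0] <= 0:
            return np.inf
        total += float(np.trace(S @ T)) - float(np.sum(np.log(evals)))
    off = lambda M: M[~np.eye(M.shape[0], dtype=bool)]
    for T in Thetas:
        total += lambda1 * float(np.abs(off(T)).sum())
    for g in range(G):
        for h in range(g + 1, G):
            total += lambda2 * float(np.abs(off(Thetas[g] - Thetas[h])).sum())
    return total


def _fused_prox_pair(
    A: np.ndarray, B: np.ndarray, a1: float, a2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact prox of a1(|x|+|y|) + a2|x-y| applied entrywise to (A, B).

    Uses the fuse-then-shrink decomposition of the two-point fused lasso:
    first pull the pair together by a2 (merging when |A-B| <= 2 a2), then
    soft-threshold both by a1.
    """
    d = A - B
    shift = np.clip(d / 2.0, -a2, a2)
    X = A - shift
    Y = B + shift
    st = lambda M: np.sign(M) * np.maximum(np.abs(M) - a1, 0.0)
    return st(X), st(Y)


def solve_fgl_oracle(
    covariances: list[np.ndarray],
    lambda1: float,
    lambda2: float,
    maxiter: int = 200000,
    tol: float = 1e-13,
) -> tuple[list[np.ndarray], float]:
    """Proximal-gradient (ISTA) minimization of the G=2 FGL objective.

    The smooth part sum_g tr(S_g Theta_g) - logdet Theta_g has gradient
    S_g - Theta_g^{-1}; the nonsmooth part separates entrywise over the
    pair, with the exact two-point fused-lasso prox on off-diagonals and
    no penalty on diagonals.  Backtracking keeps iterates positive
    definite.  Independent of the package's ADMM code path.
    """
    if len(covariances) != 2:
        raise ValueError("oracle supports G=2")
    p = covariances[0].shape[0]
    off = ~np.eye(p, dtype=bool)

    def smooth(mats):
        total = 0.0
        for T, S in zip(mats, covariances):
            evals = np.linalg.eigvalsh(T)
            if evals[0] <= 0:
                return np.inf
            total += float(np.trace(S @ T)) - float(np.sum(np.log(evals)))
        return total

    def prox(mats, t):
        A, B = mats
        Xo, Yo = _fused_prox_pair(A, B, lambda1 * t, lambda2 * t)
        X = np.where(off, Xo, A)
        Y = np.where(off, Yo, B)
        return [0.5 * (X + X.T), 0.5 * (Y + Y.T)]

    mats = [np.linalg.inv(S + 0.1 * np.eye(p)) for S in covariances]
    t = 1.0
    prev_obj = np.inf
    for _ in range(maxiter):
        f0 = smooth(mats)
        grads = [S - np.linalg.inv(T) for T, S in zip(mats, covariances)]
        while True:
            cand = prox([T - t * g for T, g in zip(mats, grads)], t)
            fc = smooth(cand)
            if np.isfinite(fc):
                dx = sum(float(np.sum((c - T) ** 2)) for c, T in zip(cand, mats))
                lin = sum(
                    float(np.sum(g * (c - T)))
                    for g, c, T in zip(grads, cand, mats)
                )
                if fc <= f0 + lin + dx / (2.0 * t) + 1e-15:
                    break
            t *= 0.5
            if t < 1e-12:
                break
        mats = cand
        obj = fgl_objective_oracle(mats, covariances, lambda1, lambda2)
        if abs(prev_obj - obj) <= tol * max(1.0, abs(obj)):
            break
        prev_obj = obj
        t = min(t * 1.2, 1.0)
    return mats, fgl_objective_oracle(mats, covariances, lambda1, lambda2)


def scalar_riht_oracle(groups: list[np.ndarray], lam: float) -> float:
    """Hand-arithmetic p=1 ridge Hotelling form for tiny datasets."""
    xs = [np.asarray(g, dtype=float).ravel() for g in groups]
    n = sum(x.size for x in xs)
    G = len(xs)
    mu = sum(x.sum() for x in xs) / n
    ss = 0.0
    for x in xs:
        ss += float(np.sum((x - x.mean()) ** 2))
    s_n = ss / (n - G)
    total = 0.0
    for x in xs:
        total += x.size * (x.mean() - mu) ** 2 / (s_n + lam)
    return total


def lasso_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    n = y.size
    return float(np.sum((y - X @ beta) ** 2) / n + lam * np.sum(np.abs(beta)))


def solve_lasso_oracle(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Smoothed-l1 L-BFGS lasso on the (1/n)||.||^2 + lam ||.||_1 scale."""
    n, p = X.shape

    def objective(beta: np.ndarray) -> float:
        r = y - X @ beta
        return float(np.sum(r * r) / n) + lam * _smooth_abs(beta)

    res = optimize.minimize(
        objective,
        np.zeros(p),
        method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return res.x
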