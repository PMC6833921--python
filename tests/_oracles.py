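"""Independent reference implementations used only by the test suite.

Everything here is deliberately naive — double loops, finite differences,
textbook update rules — so it shares no code path with the package.
"""

from __future__ import annotations

import numpy as np


def objective_loops(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """½‖A − WH‖² by explicit summation."""
    n, m = A.shape
    r = W.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(m):
            pred = sum(W[i, k] * H[k, j] for k in range(r))
            total += (A[i, j] - pred) ** 2
    return 0.5 * total


def fd_gradient(f, X: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of a matrix."""
    G = np.zeros_like(X, dtype=float)
    for idx in np.ndindex(X.shape):
        Xp = X.copy()
        Xm = X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        G[idx] = (f(Xp) - f(Xm)) / (2 * h)
    return G


def kkt_residual_cases(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Projected-gradient residual by per-entry case analysis."""
    GW = -A @ H.T + W @ H @ H.T
    GH = -W.T @ A + W.T @ W @ H
    total = 0.0
    for X, G in ((W, GW), (H, GH)):
        for idx in np.ndindex(X.shape):
            if X[idx] > 0:
                total += G[idx] ** 2
            elif G[idx] < 0:
                total += G[idx] ** 2
    return float(np.sqrt(total))


def multiplicative_updates(
    A: np.ndarray,
    W0: np.ndarray,
    H0: np.ndarray,
    iters: int = 500,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Classic multiplicative NMF updates from a given initialization."""
    W = W0.copy()
    H = H0.copy()
    for _ in range(iters):
        H *= (W.T @ A) / np.maximum(W.T @ W @ H, eps)
        W *= (A @ H.T) / np.maximum(W @ H @ H.T, eps)
    return W, H


def cg_quadratic(Q: np.ndarray, b: np.ndarray, x0: np.ndarray, iters: int):
    """Textbook conjugate gradient on ½xᵀQx − bᵀx; returns the iterate path."""
    x = x0.astype(float).copy()
    g = Q @ x - b
    d = -g
    path = [x.copy()]
    for _ in range(iters):
        if np.linalg.norm(g) == 0:
            break
        alpha = float(g @ g) / float(d @ Q @ d)
        x = x + alpha * d
        g_new = Q @ x - b
        beta = float(g_new @ g_new) / float(g @ g)
        d = -g_new + beta * d
        g = g_new
        path.append(x.copy())
    return path
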