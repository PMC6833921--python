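"""Frobenius objective, matrix gradients and the KKT stopping residual.

The factorization minimizes F(W, H) = ½‖A − WH‖²_F over W ≥ 0, H ≥ 0.
Gradients are the standard matrix forms ∇_W F = −AHᵀ + WHHᵀ and
∇_H F = −WᵀA + WᵀWH. First-order optimality is measured by the projected
gradient residual: at entries where the variable is strictly positive the
plain gradient must vanish; at entries pinned to zero only a negative
gradient (a feasible descent direction) counts as a violation.
"""

from __future__ import annotations

import numpy as np

from .errors import DimensionError

__all__ = ["objective", "grad_W", "grad_H", "inner_product", "kkt_residual"]


def _check_shapes(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> None:
    n, m = A.shape
    if W.shape[0] != n or H.shape[1] != m or W.shape[1] != H.shape[0]:
        raise DimensionError(
            f"incompatible shapes A{A.shape}, W{W.shape}, H{H.shape}"
        )


def objective(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """½‖A − WH‖²_F."""
    _check_shapes(A, W, H)
    R = A - W @ H
    return 0.5 * float(np.sum(R * R))


def grad_W(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """∂F/∂W = −AHᵀ + WHHᵀ."""
    _check_shapes(A, W, H)
    return -A @ H.T + W @ (H @ H.T)


def grad_H(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """∂F/∂H = −WᵀA + WᵀWH."""
    _check_shapes(A, W, H)
    return -W.T @ A + (W.T @ W) @ H


def inner_product(S: np.ndarray, T: np.ndarray) -> float:
    """Frobenius inner product ⟨S, T⟩ = Σ_{ij} S_ij T_ij."""
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape != T.shape:
        raise DimensionError(f"shape mismatch {S.shape} vs {T.shape}")
    return float(np.sum(S * T))


def _projected(grad: np.ndarray, X: np.ndarray) -> np.ndarray:
    # gradient where X > 0; only the negative part where X is at its bound
    return np.where(X > 0, grad, np.minimum(grad, 0.0))


def kkt_residual(A: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Projected-gradient KKT residual over both factors.

    Zero exactly at KKT points of the nonnegativity-constrained problem:
    stationarity where variables are free, complementarity where they are
    pinned at zero.
    """
    _check_shapes(A, W, H)
    if np.any(W < 0) or np.any(H < 0):
        raise ValueError("kkt_residual requires elementwise nonnegative W, H")
    pw = _projected(grad_W(A, W, H), W)
    ph = _projected(grad_H(A, W, H), H)
    return float(np.sqrt(np.sum(pw * pw) + np.sum(ph * ph)))
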