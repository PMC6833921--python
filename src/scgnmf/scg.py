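"""Modified spectral conjugate gradient solver for one ANLS subproblem.

With one factor held fixed, each subproblem of the alternating scheme is a
convex quadratic least-squares problem in the other factor. This module
minimizes it *unconstrained* (the nonnegative projection is a separate step
of the outer driver) with a conjugate-gradient-type method whose search
direction D_k = −θ_k G_k + β_k D_{k−1} mixes a spectral scaling of the
gradient with a conjugacy term. Step lengths come from Armijo-type
backtracking with an extra curvature term:

    F(X + αD) ≤ F(X) + δ1·α·⟨G, D⟩ − δ2·α²·‖D‖²,   α = ρ^l.

The spectral and conjugate parameters switch between two branches on the
test ⟨D_{k−1}, ȳ_{k−1}⟩ > η‖G_{k−1}‖², where ȳ is the gradient difference
orthogonalized against the current gradient. Directions that fail the
descent test ⟨G, D⟩ < 0 — possible in floating point or under degenerate
curvature — are replaced by steepest descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .errors import (
    DegenerateCurvatureError,
    GradientVanishedError,
    LineSearchError,
    NumericalError,
)
from .objective import inner_product

__all__ = [
    "SolverConfig",
    "SubproblemTrace",
    "initial_direction",
    "curvature_quantities",
    "spectral_params",
    "search_direction",
    "backtracking_step",
    "solve_subproblem",
]

# denominators smaller than this trigger a steepest-descent restart
_DENOM_GUARD = 1e-300


@dataclass
class SolverConfig:
    """Algorithmic constants for the inner solver and the outer alternation.

    Defaults are the published working values: delta1 = 0.4 (sufficient
    decrease), delta2 = 0.001 (curvature penalty), eta = 0.001 (branch
    threshold), rho = 0.65 (backtracking ratio), epsilon = 1e-7 (gradient
    tolerance; also the outer relative-KKT tolerance unless
    ``outer_epsilon`` overrides it).
    """

    delta1: float = 0.4
    delta2: float = 0.001
    eta: float = 0.001
    rho: float = 0.65
    epsilon: float = 1e-7
    max_inner_iter: int = 1000
    max_backtracks: int = 60
    max_outer_iter: int = 200
    outer_epsilon: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta1 < 1.0):
            raise ValueError("delta1 must lie in (0, 1)")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.delta2 <= 0 or self.epsilon <= 0:
            raise ValueError("delta2 and epsilon must be positive")

    @property
    def effective_outer_epsilon(self) -> float:
        return self.epsilon if self.outer_epsilon is None else self.outer_epsilon


@dataclass
class SubproblemTrace:
    """Diagnostics from one inner solve."""

    f_trace: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    iterations: int = 0
    restarts: int = 0
    converged: bool = False


def initial_direction(g: np.ndarray) -> np.ndarray:
    """Steepest descent: D_0 = −G."""
    return -g


def curvature_quantities(
    x_cur: np.ndarray,
    x_prev: np.ndarray,
    g_cur: np.ndarray,
    g_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterate difference s, gradient difference y and its orthogonalized ȳ.

    ȳ = y − G·⟨G, y⟩/‖G‖² is y with its component along the current
    gradient removed, so ⟨G, ȳ⟩ = 0 by construction.
    """
    gnorm2 = inner_product(g_cur, g_cur)
    if gnorm2 == 0.0:
        raise GradientVanishedError("current gradient is zero; already converged")
    s = x_cur - x_prev
    y = g_cur - g_prev
    y_bar = y - g_cur * (inner_product(g_cur, y) / gnorm2)
    return s, y, y_bar


def spectral_params(
    d_prev: np.ndarray,
    g_cur: np.ndarray,
    g_prev: np.ndarray,
    s: np.ndarray,
    y: np.ndarray,
    y_bar: np.ndarray,
    eta: float,
) -> tuple[float, float]:
    """Spectral parameter θ and conjugate parameter β.

    Main branch (taken when ⟨D_{k−1}, ȳ⟩ > η‖G_{k−1}‖²):

        θ = [⟨D,y⟩ − ⟨D,G⟩⟨G,s⟩/‖G‖²] / ⟨D,ȳ⟩
        β = [⟨G,y⟩ − ⟨G,s⟩] / ⟨D,ȳ⟩

    Fallback branch otherwise:

        θ = [⟨D,y⟩ − ⟨D,G⟩⟨G,G_prev⟩/‖G‖²] / ⟨−D,G_prev⟩
        β = ⟨G,y⟩ / ‖G_prev‖²

    Raises :class:`DegenerateCurvatureError` when the active branch's
    denominators vanish; the caller restarts with steepest descent.
    """
    gnorm2 = inner_product(g_cur, g_cur)
    gprev_norm2 = inner_product(g_prev, g_prev)
    if gnorm2 < _DENOM_GUARD or gprev_norm2 < _DENOM_GUARD:
        raise DegenerateCurvatureError("vanishing gradient norm in parameter update")

    d_ybar = inner_product(d_prev, y_bar)
    d_y = inner_product(d_prev, y)
    d_g = inner_product(d_prev, g_cur)
    g_y = inner_product(g_cur, y)

    if d_ybar > eta * gprev_norm2:
        if abs(d_ybar) < _DENOM_GUARD:
            raise DegenerateCurvatureError("main-branch denominator vanished")
        g_s = inner_product(g_cur, s)
        theta = (d_y - d_g * g_s / gnorm2) / d_ybar
        beta = (g_y - g_s) / d_ybar
    else:
        neg_d_gprev = inner_product(-d_prev, g_prev)
        if abs(neg_d_gprev) < _DENOM_GUARD:
            raise DegenerateCurvatureError("fallback denominator vanished")
        g_gprev = inner_product(g_cur, g_prev)
        theta = (d_y - d_g * g_gprev / gnorm2) / neg_d_gprev
        beta = g_y / gprev_norm2
    return theta, beta


def search_direction(
    theta: float,
    beta: float,
    g_cur: np.ndarray,
    d_prev: np.ndarray | None,
    k: int,
) -> np.ndarray:
    """D_k = −θG + βD_{k−1} for k > 0, steepest descent at k = 0.

    If the combined direction fails the descent test ⟨G, D⟩ < 0 it is
    replaced by −G, preserving the line-search precondition.
    """
    if k == 0 or d_prev is None:
        return -g_cur
    d = -theta * g_cur + beta * d_prev
    if inner_product(g_cur, d) >= 0.0:
        return -g_cur
    return d


def backtracking_step(
    f_eval: Callable[[np.ndarray], float],
    x: np.ndarray,
    d: np.ndarray,
    g: np.ndarray,
    cfg: SolverConfig,
) -> tuple[float, float]:
    """Largest α = ρ^l satisfying the sufficient-decrease inequality.

    Returns (α, F(x + αd)). The accepted step strictly decreases F by at
    least δ2·α²‖d‖² because ⟨g, d⟩ < 0 is required on entry.
    """
    gd = inner_product(g, d)
    if gd >= 0.0:
        raise ValueError(f"not a descent direction: <g, d> = {gd}")
    dnorm2 = inner_product(d, d)
    if dnorm2 == 0.0:
        raise ValueError("zero direction")
    f0 = f_eval(x)
    for l in range(cfg.max_backtracks + 1):
        alpha = cfg.rho**l
        f_new = f_eval(x + alpha * d)
        if f_new <= f0 + cfg.delta1 * alpha * gd - cfg.delta2 * alpha * alpha * dnorm2:
            return alpha, f_new
    raise LineSearchError(
        f"no acceptable step within {cfg.max_backtracks} backtracks "
        f"(|g| = {np.sqrt(inner_product(g, g)):.3e})"
    )


def solve_subproblem(
    A: np.ndarray,
    fixed: np.ndarray,
    x0: np.ndarray,
    which: Literal["W", "H"],
    cfg: SolverConfig,
) -> tuple[np.ndarray, SubproblemTrace]:
    """Minimize F over one factor with the other fixed, unconstrained.

    ``which="W"`` solves min_W ½‖A − W·fixed‖² from x0 = W_init;
    ``which="H"`` solves min_H ½‖A − fixed·H‖² from x0 = H_init.
    Iterates until ‖G‖_F ≤ epsilon or ``max_inner_iter``; nonnegativity is
    NOT enforced here (projection is the outer driver's job). The objective
    trace is strictly decreasing over accepted steps.

    Both cases reduce to min_X ½‖C − XB‖²_F (the H case via transposition),
    so the Gram matrix BBᵀ and the cross term CBᵀ are computed once and
    every objective/gradient evaluation costs O(rows·r²) instead of a full
    residual.
    """
    if which == "H":
        C, B, X = A.T, fixed.T, np.array(x0.T, dtype=float)
    elif which == "W":
        C, B, X = A, fixed, np.array(x0, dtype=float)
    else:
        raise ValueError(f"which must be 'W' or 'H', got {which!r}")

    BBt = B @ B.T
    CBt = C @ B.T
    cc = float(np.sum(C * C))

    def f_eval(Z: np.ndarray) -> float:
        # ½‖C − ZB‖² expanded through the cached Gram matrices
        return 0.5 * cc - float(np.sum(Z * CBt)) + 0.5 * float(np.sum((Z @ BBt) * Z))

    def grad(Z: np.ndarray) -> np.ndarray:
        return Z @ BBt - CBt

    def backtrack_quadratic(d: np.ndarray, g: np.ndarray) -> tuple[float, float]:
        # The subproblem is an exact quadratic, so the decrease along d is
        # α·⟨G,D⟩ + ½α²·⟨D·BBᵀ,D⟩ in closed form; testing the sufficient-
        # decrease inequality on it avoids the catastrophic cancellation a
        # full objective evaluation suffers near the optimum.
        gd = inner_product(g, d)
        if gd >= 0.0:
            raise ValueError(f"not a descent direction: <g, d> = {gd}")
        q = float(np.sum((d @ BBt) * d))
        dnorm2 = inner_product(d, d)
        for l in range(cfg.max_backtracks + 1):
            alpha = cfg.rho**l
            decrease = alpha * gd + 0.5 * alpha * alpha * q
            if decrease <= cfg.delta1 * alpha * gd - cfg.delta2 * alpha * alpha * dnorm2:
                return alpha, decrease
        raise LineSearchError(
            f"no acceptable step within {cfg.max_backtracks} backtracks "
            f"(|g| = {np.sqrt(inner_product(g, g)):.3e})"
        )

    trace = SubproblemTrace()
    g = grad(X)
    gnorm = float(np.linalg.norm(g))
    f_cur = f_eval(X)
    trace.f_trace.append(f_cur)
    trace.grad_norms.append(gnorm)

    d_prev: np.ndarray | None = None
    x_prev: np.ndarray | None = None
    g_prev: np.ndarray | None = None

    for k in range(cfg.max_inner_iter):
        if gnorm <= cfg.epsilon:
            trace.converged = True
            break
        if k == 0:
            d = initial_direction(g)
        else:
            assert x_prev is not None and g_prev is not None and d_prev is not None
            try:
                s, y, y_bar = curvature_quantities(X, x_prev, g, g_prev)
                theta, beta = spectral_params(d_prev, g, g_prev, s, y, y_bar, cfg.eta)
                d = -theta * g + beta * d_prev
                if inner_product(g, d) >= 0.0:  # descent safeguard
                    d = -g
                    trace.restarts += 1
            except DegenerateCurvatureError:
                d = -g
                trace.restarts += 1

        try:
            alpha, decrease = backtrack_quadratic(d, g)
        except LineSearchError:
            # a conjugate direction nearly orthogonal to the gradient can
            # make the sufficient-decrease test unsatisfiable within the
            # backtrack budget; steepest descent always admits a step
            if np.array_equal(d, -g):
                raise
            d = -g
            trace.restarts += 1
            alpha, decrease = backtrack_quadratic(d, g)
        f_new = f_cur + decrease
        x_prev, g_prev, d_prev = X, g, d
        X = X + alpha * d
        if not np.all(np.isfinite(X)):
            raise NumericalError(f"non-finite iterate at inner iteration {k}")
        g = grad(X)
        gnorm = float(np.linalg.norm(g))
        f_cur = f_new
        trace.f_trace.append(f_cur)
        trace.grad_norms.append(gnorm)
        trace.iterations = k + 1
    else:
        trace.converged = gnorm <= cfg.epsilon

    if gnorm <= cfg.epsilon:
        trace.converged = True
    return (X.T if which == "H" else X), trace
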